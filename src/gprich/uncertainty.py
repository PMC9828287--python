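"""Asymptotic variance and log-normal confidence intervals.

The variance of a frequency-count richness estimator is obtained by the delta
method under the approximation that the spectrum ``(f_0, f_1, ..., f_n)`` is
multinomial with total ``S``:

    var(S_hat) ~= sum_ij (dS/df_i)(dS/df_j) cov(f_i, f_j),
    cov(f_i, f_j) = f_i (1 - f_i / S_hat)   if i == j
                  = -f_i f_j / S_hat        if i != j,

which collapses to ``sum_i g_i^2 f_i - (sum_i g_i f_i)^2 / S_hat`` for
gradient ``g``.  Every observed multiplicity enters: the rare counts through
the estimator formula, all others with gradient 1 through ``S_obs``.

Because ``S_hat - S_obs`` is positive and skewed, the confidence interval
assumes ``S_hat - S_obs`` is log-normal, guaranteeing a lower bound above the
observed richness:

    [S_obs + (S_hat - S_obs)/R,  S_obs + (S_hat - S_obs) R],
    R = exp(z * sqrt(log(1 + var / (S_hat - S_obs)^2))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .estimators import ESTIMATORS, RichnessEstimate, compute_estimate
from .frequency import FrequencyCounts

__all__ = [
    "VarianceResult",
    "ConfidenceInterval",
    "variance_asymptotic",
    "ci_lognormal",
    "attach_uncertainty",
    "numeric_gradient",
]


@dataclass(frozen=True)
class VarianceResult:
    variance: float
    gradient: dict[int, float]
    method: str  # "analytic" or "numeric"
    clipped: bool = False  # quadratic form went negative and was floored at 0


@dataclass(frozen=True)
class ConfidenceInterval:
    level: float
    lower: float
    upper: float
    R: float | None  # None in the degenerate S_hat == S_obs case
    degenerate: bool = False


def _chao1_f0_partials(f1: float, f2: float) -> tuple[float, float]:
    """(d f0/d f1, d f0/d f2) for the Chao1 unseen part, active piece."""
    if f2 > 0:
        return f1 / f2, -f1 * f1 / (2.0 * f2 * f2)
    return (2.0 * f1 - 1.0) / 2.0, 0.0


def _gradient_analytic(
    fc: FrequencyCounts, estimator_id: str
) -> dict[int, float]:
    """dS_hat/df_k for every observed k, using the active formula piece.

    At the GP clamp boundaries the one-sided derivative of the active piece
    is used (the multiplier is constant inside the clamped regions), and any
    substituted f1/f3 is frozen at its substituted value.
    """
    obs = fc.nonzero()
    grad = {k: 1.0 for k in obs}  # S_obs pass-through
    f1, f2, f3 = fc[1], fc[2], fc[3]

    if estimator_id == "jackknife1":
        if 1 in grad:
            grad[1] = 2.0
        return grad

    d1, d2 = _chao1_f0_partials(f1, f2)

    if estimator_id == "chao1":
        if 1 in grad:
            grad[1] += d1
        if 2 in grad:
            grad[2] += d2
        return grad

    if estimator_id == "gp":
        f1s = f1 if f1 > 0 else 1.0
        f3s = f3 if f3 > 0 else 1.0
        A = 2.0 * f2 * f2 / (3.0 * f1s * f3s)
        if A >= 1.0 or A <= 0.5:
            mult = 1.0 if A >= 1.0 else 1.5
            if 1 in grad:
                grad[1] += mult * d1
            if 2 in grad:
                grad[2] += mult * d2
            return grad
        # interior piece: S = S_obs + f0 * (2 - A); substituted counts frozen
        f0 = f1 * f1 / (2.0 * f2) if f2 > 0 else f1 * (f1 - 1.0) / 2.0
        mult = 2.0 - A
        dA_df1 = -A / f1 if f1 > 0 else 0.0
        dA_df2 = 2.0 * A / f2 if f2 > 0 else 0.0
        dA_df3 = -A / f3 if f3 > 0 else 0.0
        if 1 in grad:
            grad[1] += mult * d1 - f0 * dA_df1
        if 2 in grad:
            grad[2] += mult * d2 - f0 * dA_df2
        if 3 in grad:
            grad[3] += -f0 * dA_df3
        return grad

    if estimator_id == "lb":
        f1s = f1 if f1 > 0 else 1.0
        f3s = f3 if f3 > 0 else 1.0
        f2m = f2 if f2 > 0 else 1.0
        f0 = f1 * f1 / (2.0 * f2) if f2 > 0 else f1 * (f1 - 1.0) / 2.0
        mult = 3.0 * f1s * f3s / (2.0 * f2m * f2m)
        dm_df1 = mult / f1 if f1 > 0 else 0.0
        dm_df2 = -2.0 * mult / f2 if f2 > 0 else 0.0
        dm_df3 = mult / f3 if f3 > 0 else 0.0
        if 1 in grad:
            grad[1] += mult * d1 + f0 * dm_df1
        if 2 in grad:
            grad[2] += mult * d2 + f0 * dm_df2
        if 3 in grad:
            grad[3] += f0 * dm_df3
        return grad

    raise ValueError(f"no analytic gradient for estimator {estimator_id!r}")


def numeric_gradient(
    fc: FrequencyCounts, estimator_id: str, rel_step: float = 1e-4
) -> dict[int, float]:
    """Central finite-difference gradient over every observed f_k.

    Step ``rel_step * max(1, f_k)``.  Used as the production gradient for
    Chao-Bunge (whose closed form involves the whole spectrum) and as a
    cross-check oracle for the analytic gradients.
    """
    fn = ESTIMATORS[estimator_id]
    obs = fc.nonzero()
    grad: dict[int, float] = {}
    for k, v in obs.items():
        h = rel_step * max(1.0, v)
        up = dict(fc.f)
        dn = dict(fc.f)
        up[k] = v + h
        dn[k] = max(v - h, 0.0)
        hi = fn(FrequencyCounts(up)).point
        lo = fn(FrequencyCounts(dn)).point
        grad[k] = (hi - lo) / (up[k] - dn[k])
    return grad


def variance_asymptotic(
    fc: FrequencyCounts, estimator_id: str, point: float | None = None
) -> VarianceResult:
    """Delta-method variance of an estimator on the given spectrum.

    ``point`` defaults to the estimator's own value (the plug-in total for
    the multinomial covariance).  Undefined estimates (e.g. Chao-Bunge with
    non-positive theta) yield a ValueError upstream of any arithmetic.
    """
    if point is None:
        point = compute_estimate(fc, estimator_id).point
    if not math.isfinite(point):
        raise ValueError(
            f"estimator {estimator_id!r} is undefined on this spectrum; "
            "no variance available"
        )
    if point <= 0:
        raise ValueError(f"plug-in total must be positive, got {point}")
    if estimator_id == "chao_bunge":
        grad = numeric_gradient(fc, estimator_id)
        method = "numeric"
    else:
        grad = _gradient_analytic(fc, estimator_id)
        method = "analytic"
    s1 = sum(g * g * fc[k] for k, g in grad.items())
    s2 = sum(g * fc[k] for k, g in grad.items())
    var = s1 - s2 * s2 / point
    clipped = var < 0
    return VarianceResult(max(var, 0.0), grad, method, clipped)


def ci_lognormal(
    s_obs: float,
    point: float,
    variance: float,
    level: float = 0.95,
    z: float | None = None,
) -> ConfidenceInterval:
    """Log-normal-transformed confidence interval for total richness.

    The default z is exactly 1.96 at level 0.95; other levels use the
    corresponding normal quantile.  When ``point == s_obs`` (no unseen part)
    the interval degenerates to ``[S_obs, S_obs]``.
    """
    if variance < 0:
        raise ValueError(f"variance must be non-negative, got {variance}")
    if point < s_obs:
        raise ValueError(f"point {point} below observed richness {s_obs}")
    d = point - s_obs
    if d == 0.0:
        return ConfidenceInterval(level, s_obs, s_obs, None, degenerate=True)
    if z is None:
        z = 1.96 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    R = math.exp(z * math.sqrt(math.log1p(variance / (d * d))))
    return ConfidenceInterval(level, s_obs + d / R, s_obs + d * R, R)


def attach_uncertainty(
    fc: FrequencyCounts, estimate: RichnessEstimate, level: float = 0.95
) -> RichnessEstimate:
    """Return a copy of ``estimate`` with s.e. and CI filled in.

    Undefined estimates pass through unchanged (no variance exists).
    """
    if not estimate.defined:
        return estimate
    vr = variance_asymptotic(fc, estimate.estimator_id, estimate.point)
    ci = ci_lognormal(estimate.s_obs, estimate.point, vr.variance, level)
    return RichnessEstimate(
        estimate.estimator_id,
        estimate.point,
        estimate.s_obs,
        estimate.diagnostics,
        se=math.sqrt(vr.variance),
        ci=(ci.lower, ci.upper),
        ci_level=level,
        provenance=estimate.provenance,
    )
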