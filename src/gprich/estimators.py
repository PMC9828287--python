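"""Point estimators of total species richness.

All estimators consume a :class:`~gprich.frequency.FrequencyCounts` spectrum
and return a :class:`RichnessEstimate`.  The headline estimator is the
Gamma-Poisson moment estimator ``estimate_gp``: each species' detection rate
is modelled as Gamma(alpha, beta) so that its sample count is marginally
negative binomial, and the shape alpha is estimated from the singleton,
doubleton and tripleton counts alone.  The resulting unseen-richness estimate
is a bias-corrected Chao1:

    S_GP = S_obs + f0.Chao1 * (2 - (2 f2^2 / (3 f1 f3))^-)

where ``f0.Chao1 = f1^2/(2 f2)`` (or ``f1(f1-1)/2`` when ``f2 = 0``) and
``(A)^-`` clamps the ratio to ``[1/2, 1]``.  The multiplier therefore lies in
``[1, 1.5]``, so S_GP always sits between Chao1 and Chao1 with its unseen
part inflated by half.

Comparison estimators: Chao1 (lower bound), first-order jackknife, the
Chao-Bunge Gamma-Poisson estimator, and the negative-binomial Taylor-expansion
estimator ``estimate_lb``.  A zero-truncated maximum-likelihood fit is also
provided (``fit_mle``) but is excluded from the default simulation battery
because of its well-known divergence problems on sparse samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .frequency import FrequencyCounts

__all__ = [
    "GammaPoissonParams",
    "EstimatorDiagnostics",
    "RichnessEstimate",
    "gamma_poisson_pmf",
    "expected_freq_counts",
    "alpha_hat_moment",
    "estimate_chao1",
    "estimate_jackknife1",
    "estimate_chao_bunge",
    "estimate_lb",
    "estimate_gp",
    "fit_mle",
    "ESTIMATORS",
    "DEFAULT_ESTIMATORS",
    "compute_estimate",
]


@dataclass(frozen=True)
class GammaPoissonParams:
    """Shape/scale parameters of the Gamma mixing distribution.

    ``p0 = (beta/(beta+1))**alpha`` is the probability that a species is
    missed entirely under the mixture.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be a positive finite real, got {self.alpha}")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be a positive finite real, got {self.beta}")

    @property
    def p0(self) -> float:
        return math.exp(self.alpha * math.log(self.beta / (self.beta + 1.0)))


@dataclass(frozen=True)
class EstimatorDiagnostics:
    """Intermediate quantities and substitution flags for one estimate.

    ``A`` is the raw doubleton ratio ``2 f2^2 / (3 f1 f3)`` (after any
    f1/f3 substitution), ``A_clamped`` the value actually used after the
    ``[1/2, 1]`` clamp.  ``fallbacks`` records which well-definedness rules
    fired; an empty set means the plain formulas applied.
    """

    alpha_hat: float | None = None
    A: float | None = None
    A_clamped: float | None = None
    theta_hat: float | None = None
    multiplier: float | None = None
    fallbacks: frozenset[str] = frozenset()


@dataclass(frozen=True)
class RichnessEstimate:
    """A point estimate of total richness with provenance.

    ``point`` is ``S_obs + f0_hat`` and is ``nan`` when the estimator is
    undefined on the given spectrum (flagged in diagnostics); standard error
    and confidence interval are attached downstream by the uncertainty
    module.
    """

    estimator_id: str
    point: float
    s_obs: float
    diagnostics: EstimatorDiagnostics = EstimatorDiagnostics()
    se: float | None = None
    ci: tuple[float, float] | None = None
    ci_level: float | None = None
    provenance: str = ""

    @property
    def f0_hat(self) -> float:
        return self.point - self.s_obs

    @property
    def defined(self) -> bool:
        return math.isfinite(self.point)


def gamma_poisson_pmf(k, params: GammaPoissonParams):
    """Marginal pmf of a species' sample count under the mixture.

    ``p_k = Gamma(alpha+k)/(k! Gamma(alpha)) * (beta/(beta+1))^alpha
    * (1/(beta+1))^k`` — a negative binomial with size ``alpha`` and success
    probability ``beta/(beta+1)``.  Evaluated in log space; ``k`` may be a
    scalar or array of non-negative integers.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr != np.floor(k_arr)):
        raise ValueError("k must contain non-negative integers")
    a, b = params.alpha, params.beta
    logp = (
        special.gammaln(a + k_arr)
        - special.gammaln(k_arr + 1.0)
        - special.gammaln(a)
        + a * math.log(b / (b + 1.0))
        - k_arr * math.log(b + 1.0)
    )
    out = np.exp(logp)
    return float(out) if np.isscalar(k) else out


def expected_freq_counts(
    S: float, params: GammaPoissonParams, k_max: int
) -> np.ndarray:
    """Expected spectrum ``E[f_k] = S * p_k`` for ``k = 0 .. k_max``."""
    if S <= 0:
        raise ValueError(f"S must be positive, got {S}")
    return S * gamma_poisson_pmf(np.arange(k_max + 1), params)


def _rare_counts(fc: FrequencyCounts) -> tuple[float, float, float]:
    return fc[1], fc[2], fc[3]


def _substituted(f1: float, f3: float) -> tuple[float, float, set[str]]:
    # f3 (or f1) is replaced by 1 when zero so the doubleton ratio stays
    # well defined; f0.Chao1 keeps its own f2 = 0 rule.
    flags: set[str] = set()
    if f3 == 0:
        f3 = 1.0
        flags.add("f3_substituted")
    if f1 == 0:
        f1 = 1.0
        flags.add("f1_substituted")
    return f1, f3, flags


def alpha_hat_moment(fc: FrequencyCounts) -> tuple[float, EstimatorDiagnostics]:
    """Moment estimate of the Gamma shape from (f1, f2, f3).

    ``alpha_hat = (4 f2^2 - 3 f1 f3) / (3 f1 f3 - 2 f2^2)``, applying the
    f1/f3 -> 1 substitutions first.  Positive exactly when ``3 f1 f3`` lies
    in ``(2 f2^2, 4 f2^2)``; outside that range the value is returned as-is
    (it may be negative), and a zero denominator yields ``nan`` with a flag.
    """
    f1, f2, f3 = _rare_counts(fc)
    f1s, f3s, flags = _substituted(f1, f3)
    num = 4.0 * f2 * f2 - 3.0 * f1s * f3s
    den = 3.0 * f1s * f3s - 2.0 * f2 * f2
    if den == 0.0:
        flags.add("alpha_undefined")
        return math.nan, EstimatorDiagnostics(
            alpha_hat=None, fallbacks=frozenset(flags)
        )
    a = num / den
    if not a > 0:
        flags.add("alpha_out_of_range")
    return a, EstimatorDiagnostics(alpha_hat=a, fallbacks=frozenset(flags))


def _f0_chao1(f1: float, f2: float) -> tuple[float, set[str]]:
    if f2 > 0:
        return f1 * f1 / (2.0 * f2), set()
    return f1 * (f1 - 1.0) / 2.0, {"f2_zero_fallback"}


def estimate_chao1(fc: FrequencyCounts) -> RichnessEstimate:
    """Chao1 lower-bound estimator ``S_obs + f1^2/(2 f2)``.

    When ``f2 = 0`` the unseen part falls back to ``f1(f1-1)/2``.
    """
    f1, f2, _ = _rare_counts(fc)
    f0, flags = _f0_chao1(f1, f2)
    return RichnessEstimate(
        "chao1",
        fc.s_obs + f0,
        fc.s_obs,
        EstimatorDiagnostics(fallbacks=frozenset(flags)),
        provenance=fc.summary(),
    )


def estimate_jackknife1(fc: FrequencyCounts) -> RichnessEstimate:
    """First-order jackknife, ``S_obs + f1``."""
    return RichnessEstimate(
        "jackknife1", fc.s_obs + fc[1], fc.s_obs, provenance=fc.summary()
    )


def estimate_chao_bunge(fc: FrequencyCounts) -> RichnessEstimate:
    """Chao-Bunge Gamma-Poisson estimator using the full spectrum.

    ``theta_hat = 1 - f1 * sum(X_i^2) / n^2`` estimates the probability a
    species is seen at least twice; the estimate is
    ``sum_{k>=2} f_k / theta_hat``.  When ``theta_hat <= 0`` (sparse data)
    the estimate is undefined and flagged rather than reported.
    """
    n = fc.n
    if n <= 0:
        raise ValueError("Chao-Bunge requires n > 0")
    f1 = fc[1]
    theta = 1.0 - f1 * fc.sum_sq / (n * n)
    tail = sum(v for k, v in fc.f.items() if k >= 2)
    if theta <= 0.0:
        return RichnessEstimate(
            "chao_bunge",
            math.nan,
            fc.s_obs,
            EstimatorDiagnostics(
                theta_hat=theta, fallbacks=frozenset({"theta_nonpositive"})
            ),
            provenance=fc.summary(),
        )
    return RichnessEstimate(
        "chao_bunge",
        tail / theta,
        fc.s_obs,
        EstimatorDiagnostics(theta_hat=theta),
        provenance=fc.summary(),
    )


def estimate_lb(fc: FrequencyCounts) -> RichnessEstimate:
    """Negative-binomial Taylor-expansion estimator.

    ``S_obs + (f1^2 / 2 f2) * (3 f1 f3 / 2 f2^2)`` — Chao1 with its unseen
    part multiplied by the inverse doubleton ratio ``1/A``.  The same f1/f3
    substitutions as the GP estimator keep the multiplier defined, and
    ``f2 -> 1`` in the multiplier when ``f2 = 0``.
    """
    f1, f2, f3 = _rare_counts(fc)
    f0, flags = _f0_chao1(f1, f2)
    f1s, f3s, sub_flags = _substituted(f1, f3)
    flags |= sub_flags
    f2m = f2 if f2 > 0 else 1.0
    mult = 3.0 * f1s * f3s / (2.0 * f2m * f2m)
    return RichnessEstimate(
        "lb",
        fc.s_obs + f0 * mult,
        fc.s_obs,
        EstimatorDiagnostics(multiplier=mult, fallbacks=frozenset(flags)),
        provenance=fc.summary(),
    )


def estimate_gp(fc: FrequencyCounts) -> RichnessEstimate:
    """Gamma-Poisson moment estimator (the headline method).

    ``S_obs + f0.Chao1 * (2 - (A)^-)`` with ``A = 2 f2^2 / (3 f1 f3)``;
    ``(A)^- = 1`` if ``A >= 1`` else ``max(1/2, A)``.  Always well defined:
    f3 (or f1) is replaced by 1 when zero, and f0.Chao1 has its own f2 = 0
    rule.  The multiplier lies in ``[1, 1.5]``.
    """
    f1, f2, f3 = _rare_counts(fc)
    f0, flags = _f0_chao1(f1, f2)
    f1s, f3s, sub_flags = _substituted(f1, f3)
    flags |= sub_flags
    A = 2.0 * f2 * f2 / (3.0 * f1s * f3s)
    A_cl = 1.0 if A >= 1.0 else max(0.5, A)
    mult = 2.0 - A_cl
    alpha, _ = alpha_hat_moment(fc)
    return RichnessEstimate(
        "gp",
        fc.s_obs + f0 * mult,
        fc.s_obs,
        EstimatorDiagnostics(
            alpha_hat=None if math.isnan(alpha) else alpha,
            A=A,
            A_clamped=A_cl,
            multiplier=mult,
            fallbacks=frozenset(flags),
        ),
        provenance=fc.summary(),
    )


def _truncated_negloglik(log_params: np.ndarray, ks: np.ndarray, fs: np.ndarray) -> float:
    a, b = np.exp(log_params)
    params = GammaPoissonParams(float(a), float(b))
    logpk = (
        special.gammaln(a + ks)
        - special.gammaln(ks + 1.0)
        - special.gammaln(a)
        + a * math.log(b / (b + 1.0))
        - ks * math.log(b + 1.0)
    )
    p0 = params.p0
    if p0 >= 1.0:
        return math.inf
    return float(-(fs * (logpk - math.log1p(-p0))).sum())


def fit_mle(
    fc: FrequencyCounts,
    init: GammaPoissonParams | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[GammaPoissonParams, RichnessEstimate]:
    """Zero-truncated maximum-likelihood fit of (alpha, beta).

    Maximises ``sum_k f_k log(p_k / (1 - p0))`` over log-parameters and
    returns the Horvitz-Thompson richness estimate ``S_obs / (1 - p0_hat)``.
    Non-convergence or a boundary escape (alpha beyond ~1e6 or below ~1e-6)
    is reported via the ``mle_nonconvergence`` / ``mle_boundary`` flags with
    a nan point, never a silent answer.  Experimental: excluded from the
    default simulation battery.
    """
    spec = fc.nonzero()
    if fc.s_obs < 2 or len(spec) < 2:
        raise ValueError(
            "MLE needs at least two species and two distinct multiplicities"
        )
    ks = np.array(list(spec.keys()), dtype=float)
    fs = np.array(list(spec.values()), dtype=float)
    if init is None:
        a0, _ = alpha_hat_moment(fc)
        a0 = a0 if math.isfinite(a0) and a0 > 0 else 1.0
        mean_k = float((ks * fs).sum() / fs.sum())
        b0 = max(a0 / mean_k, 1e-3)  # mixture mean alpha/beta ~ mean count
        init = GammaPoissonParams(a0, b0)
    res = optimize.minimize(
        _truncated_negloglik,
        x0=np.log([init.alpha, init.beta]),
        args=(ks, fs),
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxiter": max_iter},
    )
    a_hat, b_hat = (float(x) for x in np.exp(res.x))
    flags: set[str] = set()
    if not res.success:
        flags.add("mle_nonconvergence")
    if not (1e-6 < a_hat < 1e6):
        flags.add("mle_boundary")
    params = GammaPoissonParams(
        min(max(a_hat, 1e-6), 1e6), min(max(b_hat, 1e-9), 1e9)
    )
    point = fc.s_obs / (1.0 - params.p0) if not flags else math.nan
    est = RichnessEstimate(
        "mle",
        point,
        fc.s_obs,
        EstimatorDiagnostics(alpha_hat=a_hat, fallbacks=frozenset(flags)),
        provenance=fc.summary(),
    )
    return params, est


ESTIMATORS = {
    "chao1": estimate_chao1,
    "jackknife1": estimate_jackknife1,
    "chao_bunge": estimate_chao_bunge,
    "lb": estimate_lb,
    "gp": estimate_gp,
}

#: The five estimators used in the simulation battery (MLE excluded).
DEFAULT_ESTIMATORS = ("chao1", "jackknife1", "chao_bunge", "lb", "gp")


def compute_estimate(fc: FrequencyCounts, estimator_id: str) -> RichnessEstimate:
    """Dispatch a point estimate by estimator id."""
    try:
        fn = ESTIMATORS[estimator_id]
    except KeyError:
        raise ValueError(
            f"unknown estimator {estimator_id!r}; choose from {sorted(ESTIMATORS)}"
        ) from None
    return fn(fc)
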