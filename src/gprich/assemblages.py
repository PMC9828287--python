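"""Ground-truth assemblages and the multinomial sampler.

An :class:`Assemblage` is a known species pool: the true richness ``S`` and a
detection-probability vector ``p`` summing to one, whose coefficient of
variation (CV = sd/mean, population convention) indexes compositional
heterogeneity.  Seven classical species-abundance models are provided, from
perfectly even (CV = 0) to a power-decay tail (CV ~ 4):

====================  =======================================  ==========
model id              construction                              CV (S=1000)
====================  =======================================  ==========
homogeneous           p_i = 1/S                                 0
uniform               a_i ~ Uniform(0, 1)                       ~0.56
negbin                a_i ~ NegBin(mean 98, variance 4900)      ~0.74
broken_stick          a_i ~ Exponential(1)                      ~1.0
lognormal             a_i ~ LogNormal(0, 1)                     ~1.3-1.6
zipf_mandelbrot       p_i proportional to 1/(i + 10)            1.88
power_decay           p_i proportional to 1/i^0.9               3.99
====================  =======================================  ==========

Stochastic models draw one weight vector per (model, S, seed) realization;
that realization is then reused across all replicates and sample sizes, so a
simulation table is conditional on a single true composition, as in field
benchmarking practice.  Sampling is multinomial with fixed total ``n``
(individuals sampled with replacement), matching sample-size-indexed
evaluation even though the estimators are derived under Poisson counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .frequency import FrequencyCounts

__all__ = [
    "Assemblage",
    "Sample",
    "MODEL_IDS",
    "make_assemblage",
    "empirical_assemblage",
    "sample_multinomial",
    "cv_of_probs",
    "geometric_tail_allocation",
]

MODEL_IDS = (
    "homogeneous",
    "uniform",
    "negbin",
    "broken_stick",
    "lognormal",
    "zipf_mandelbrot",
    "power_decay",
)

_DETERMINISTIC = frozenset({"homogeneous", "zipf_mandelbrot", "power_decay"})


def cv_of_probs(p: np.ndarray) -> float:
    """Coefficient of variation sd(p)/mean(p), population (1/S) convention."""
    p = np.asarray(p, dtype=float)
    return float(p.std() / p.mean())


@dataclass(frozen=True)
class Assemblage:
    """True species pool: richness S and detection probabilities p."""

    S: int
    p: np.ndarray
    model_id: str
    realization_seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if len(p) != self.S:
            raise ValueError(f"p has length {len(p)}, expected S={self.S}")
        if np.any(p <= 0):
            raise ValueError("all detection probabilities must be positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"p sums to {p.sum()!r}, expected 1")
        p = p.copy()
        p.flags.writeable = False
        object.__setattr__(self, "p", p)

    @property
    def cv(self) -> float:
        return cv_of_probs(self.p)

    def to_text(self) -> str:
        """Two-column ``species_index,p`` export for reproducibility audits."""
        lines = [f"# model={self.model_id} S={self.S} cv={self.cv:.6f}"]
        lines += [f"{i + 1},{pi:.17g}" for i, pi in enumerate(self.p)]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class Sample:
    """One multinomial draw from an assemblage: per-species counts X_i."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return int((self.counts > 0).sum())

    def frequency_counts(self) -> FrequencyCounts:
        pos = self.counts[self.counts > 0]
        tally = np.bincount(pos.astype(np.int64))
        return FrequencyCounts(
            {int(k): float(v) for k, v in enumerate(tally) if k >= 1 and v > 0}
        )


def _draw_weights(model_id: str, S: int, rng: np.random.Generator) -> np.ndarray:
    i = np.arange(1, S + 1, dtype=float)
    if model_id == "homogeneous":
        return np.full(S, 1.0)
    if model_id == "uniform":
        return rng.uniform(0.0, 1.0, S)
    if model_id == "negbin":
        # mean 98, variance 4900 -> size r = 98^2/(4900-98) = 2, prob 0.02;
        # zero draws are redrawn since a species cannot carry zero weight
        r, q = 2.0, 0.02
        a = rng.negative_binomial(r, q, S).astype(float)
        while np.any(a == 0):
            idx = a == 0
            a[idx] = rng.negative_binomial(r, q, int(idx.sum())).astype(float)
        return a
    if model_id == "broken_stick":
        return rng.exponential(1.0, S)
    if model_id == "lognormal":
        return rng.lognormal(0.0, 1.0, S)
    if model_id == "zipf_mandelbrot":
        return 1.0 / (i + 10.0)
    if model_id == "power_decay":
        return 1.0 / i**0.9
    raise ValueError(f"unknown model {model_id!r}; choose from {MODEL_IDS}")


def make_assemblage(model_id: str, S: int, seed: int | None = None) -> Assemblage:
    """Build an assemblage from one of the seven abundance models.

    Stochastic models (uniform, negbin, broken_stick, lognormal) require a
    seed and return the same weight realization for the same (model, S,
    seed); the deterministic models ignore the seed.
    """
    if S < 2:
        raise ValueError(f"S must be >= 2, got {S}")
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}; choose from {MODEL_IDS}")
    if model_id in _DETERMINISTIC:
        rng = np.random.default_rng(0)  # never consulted
    else:
        if seed is None:
            raise ValueError(f"model {model_id!r} is stochastic and needs a seed")
        rng = np.random.default_rng(seed)
    a = _draw_weights(model_id, S, rng)
    return Assemblage(S, a / a.sum(), model_id, realization_seed=seed)


def geometric_tail_allocation(
    n_species: int, total: int, k_min: int, ratio: float = 0.7
) -> list[int]:
    """Deterministic integer abundances for an aggregated spectrum tail.

    Splits ``total`` individuals over ``n_species`` species, each with at
    least ``k_min`` individuals, by distributing the surplus with geometric
    weights ``ratio**i`` and largest-remainder rounding.  Used to expand
    cells like "15 species observed >= 15 times" into concrete abundances;
    any such allocation is a modelling convenience and downstream summaries
    of the rare counts f1..f3 never depend on it.
    """
    if n_species == 0:
        if total != 0:
            raise ValueError("no tail species but a nonzero tail total")
        return []
    surplus = total - n_species * k_min
    if surplus < 0:
        raise ValueError(
            f"tail total {total} cannot give {n_species} species >= {k_min} each"
        )
    w = ratio ** np.arange(n_species)
    w /= w.sum()
    extra = np.floor(w * surplus).astype(int)
    short = surplus - int(extra.sum())
    rem = w * surplus - extra
    for idx in np.argsort(-rem)[:short]:
        extra[idx] += 1
    out = sorted((k_min + int(e) for e in extra), reverse=True)
    assert sum(out) == total
    return out


def empirical_assemblage(
    fc: FrequencyCounts,
    tail_species: int = 0,
    tail_total: int = 0,
    tail_k_min: int = 0,
    model_id: str = "empirical",
) -> Assemblage:
    """Treat an observed spectrum as the true assemblage.

    The relative abundances become the detection probabilities.  When the
    source spectrum carries an aggregated tail ("x species with >= k_min
    individuals summing to tail_total"), the tail is expanded by
    :func:`geometric_tail_allocation`.
    """
    if not fc.is_integral:
        raise ValueError("empirical assemblage requires an integer spectrum")
    counts: list[int] = []
    for k, v in fc.nonzero().items():
        counts.extend([k] * int(v))
    if tail_species:
        counts.extend(geometric_tail_allocation(tail_species, tail_total, tail_k_min))
    x = np.array(counts, dtype=float)
    if len(x) < 2:
        raise ValueError("assemblage needs at least two species")
    return Assemblage(len(x), x / x.sum(), model_id)


def sample_multinomial(
    assemblage: Assemblage, n: int, rng: np.random.Generator
) -> Sample:
    """Draw a fixed-size sample of individuals with replacement."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    return Sample(rng.multinomial(n, assemblage.p))
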