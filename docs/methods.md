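# Methods

## Model and estimators

Individual-based abundance sampling: S species, species i contributing a
count Xᵢ, with the species observed iff Xᵢ > 0. The frequency counts
f_k = #{i : Xᵢ = k} are the sufficient statistic for every method in the
package; f₀ (unseen species) is the estimand. Under the Gamma–Poisson
mixture, Xᵢ ~ Poisson(λᵢ) with λᵢ ~ Gamma(shape α, scale β), the marginal
pmf is negative binomial,

    p_k = Γ(α+k)/(k! Γ(α)) (β/(β+1))^α (1/(β+1))^k ,

so E[f_k] = S·p_k. The expected-count ratios give the moment identity
α = (4E[f₂]² − 3E[f₁]E[f₃]) / (3E[f₁]E[f₃] − 2E[f₂]²), whose plug-in
version α̂ uses the observed rare counts. The GP estimator bounds the
resulting bias correction of Chao1:

    Ŝ_GP = S_obs + f̂₀.Chao1 (2 − (A)⁻),  A = 2f₂²/(3f₁f₃),

with (A)⁻ = 1 if A ≥ 1 and max(½, A) otherwise. The mixture nests the
broken-stick model (α = 1) and the homogeneous model (α → ∞); under
homogeneity 2E[f₂]² = 3E[f₁]E[f₃], the clamp is active at 1, and Ŝ_GP
coincides with Chao1.

Well-definedness rules: f₃ → 1 if f₃ = 0 and f₁ → 1 if f₁ = 0 inside the
ratio A only; f̂₀.Chao1 switches to f₁(f₁−1)/2 when f₂ = 0. The LB
estimator (Ŝ_LB = S_obs + (f₁²/2f₂)(3f₁f₃/2f₂²)) shares these rules and
additionally substitutes f₂ → 1 inside its multiplier when f₂ = 0, since
unlike the GP clamp nothing else bounds it. Every substitution is recorded
in the estimate's diagnostics flags.

Chao–Bunge is implemented with θ̂ = 1 − f₁ΣXᵢ²/n². The n² in the
denominator is fixed by an exact oracle: on the expected spectrum of a
homogeneous Poisson(2) assemblage with S = 1000, n = 2000, this convention
gives θ̂ ≈ 0.594 and Ŝ_CB ≈ 1000, the only dimensionally consistent
reading (θ̂ estimates P(Xᵢ ≥ 2), a probability). θ̂ ≤ 0 yields an undefined
estimate with a `theta_nonpositive` flag, never a negative richness.

The zero-truncated MLE (Horvitz–Thompson form S_obs/(1 − p̂₀)) is provided
but flagged experimental: at mean counts below ~1 the truncated likelihood
is nearly flat along an (α, β) ridge and the fit is not identifiable in any
practical sense; it is excluded from the default simulation battery.

## Uncertainty

Variances come from the delta method treating (f₀, f₁, …) as multinomial
with total Ŝ: var(Ŝ) = Σ gᵢ² fᵢ − (Σ gᵢ fᵢ)²/Ŝ with gᵢ = ∂Ŝ/∂fᵢ. Gradients
are analytic for Chao1, jackknife, LB and GP — every observed multiplicity
contributes at least the S_obs pass-through term gᵢ = 1 — and central
finite differences (step 10⁻⁴·max(1, f_k)) for Chao–Bunge, whose dependence
on the whole spectrum makes hand derivatives error-prone. At the GP clamp
boundaries the one-sided derivative of the active piece is used (multiplier
derivative zero inside the clamped regions), matching the estimator
actually computed; substituted counts are held constant. A numerically
negative quadratic form (possible with the plug-in Ŝ on tiny samples) is
floored at zero and flagged so batch runs never abort.

The CI assumes Ŝ − S_obs is log-normal:
[S_obs + (Ŝ−S_obs)/R, S_obs + (Ŝ−S_obs)·R] with
R = exp{z·√log(1 + var/(Ŝ−S_obs)²)}; z is exactly 1.96 at the default 0.95
level (the conventional constant rather than the fuller-precision
quantile), and other levels use the corresponding normal quantile. The
lower bound is ≥ S_obs by construction; Ŝ = S_obs degenerates to the point
interval [S_obs, S_obs].

## Synthetic assemblages

`make_assemblage` builds the seven standard abundance models at any S
(defaults in the benchmarking scripts: S = 1000). Stochastic models draw
the weight vector once per (model, S, seed) and reuse that single
realization across all replicates and sample sizes, so a results table is
conditional on one true composition — the realized CV is reported alongside.
The negative-binomial model targets weight mean 98 and variance 4900 (size
2, success probability 0.02); zero draws are redrawn because a species
cannot carry zero weight. Sampling is multinomial with fixed n (individuals
drawn with replacement): the estimators' Poisson derivation and fixed-n
sampling agree asymptotically, and fixed n matches sample-size-indexed
reporting. Replicate r at size n uses the child stream SeedSequence([seed,
n, r]), making results independent of execution order.

What the generator does *not* emulate: detection covariates, taxonomic
misidentification, sequencing error, spatial/temporal aggregation of
individuals, or sample-based (incidence) designs. Passing benchmarks here
shows estimator behaviour under idealized multinomial sampling from a fixed
composition, not robustness to those real-data complications.

Empirical assemblages treat observed relative abundances as true detection
probabilities. Packaged survey rows aggregate species seen ≥ 15 times into
one tail cell; resampling needs concrete tail abundances, which are
reconstructed deterministically (surplus above the 15-per-species floor
split by geometric weights, ratio 0.7, largest-remainder rounding). The
rare counts f₁..f₃ — all that the estimators' corrections use — never
depend on this allocation; only the resampled tail shape does, mildly
(e.g. the vascular assemblage's reconstructed CV is 1.60 against 1.56
computed from the original full data).

## Evaluation harness

Per (sample size, estimator): average estimate, bias against the true S of
the generating assemblage, sample s.e. (ddof = 1), mean asymptotic s.e.,
RMSE, and CI coverage of the true S. Undefined estimates are excluded from
all averages and reported as a failure count; `cb_raw=True` instead keeps
raw Chao–Bunge ratios even at θ̂ ≤ 0, reproducing the inflated averages
naive raw averaging produces on sparse heterogeneous samples. Problem sizes
in the shipped tests and scripts: S = 1000 with 1,000 replicates for the
headline cells (seconds of runtime); unit and property tests use 150–500
replicates or smaller assemblages.

## Numerical choices

All gamma-function arithmetic in log space; estimates are reals, never
rounded to integers. Frequency spectra are stored sparsely and accept
real-valued entries so that exact expected-count spectra can be fed through
the same estimator code (the moment-identity and Chao–Bunge oracles);
file readers and empirical assemblages enforce integer counts. The mean of
the GP estimate over replicates is mildly sensitive to samples whose ratio
A lands near the clamp at 1 (about a third of replicates on a heavy-tailed
assemblage at large n): the one-sided clamp rule adopted here resolves
those ties toward the Chao1 piece, and any implementation choosing a
different tie treatment will differ by a few species in such cells.

## Known limitations

Abundance data only (no incidence designs); no coverage-based (ACE-family)
or second-order jackknife comparators; no bootstrap or profile-likelihood
intervals; the MLE is reported for completeness but should not be trusted
on sparse samples. Estimates inherit the usual caveat of all unseen-species
methods: they extrapolate from the rare tail and say nothing about species
whose detection probability is effectively zero under the survey design.
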