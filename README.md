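# gprich

Species richness estimation from abundance frequency counts.

Field surveys almost never detect every species present: the observed
richness S_obs underestimates the true richness S, badly so for small
samples or strongly uneven communities. `gprich` is for ecologists,
microbiome researchers and biostatisticians who need to estimate the number
of *unseen* species f₀ from a single sample of individuals, together with a
defensible standard error and confidence interval — and to benchmark
competing estimators on assemblages whose true richness is known.

## The estimator

All methods here consume only the frequency counts f_k — the number of
species observed exactly k times. The headline estimator models each
species' detection rate λᵢ as Gamma(α, β), so the species' sample count is
marginally negative binomial. Estimating α by the method of moments from
the rare counts alone,

    α̂ = (4f₂² − 3f₁f₃) / (3f₁f₃ − 2f₂²),

and bounding the resulting bias correction for stability gives the
Gamma–Poisson (GP) richness estimator

    Ŝ_GP = S_obs + f̂₀.Chao1 · (2 − (A)⁻),   A = 2f₂² / (3f₁f₃),

where f̂₀.Chao1 = f₁²/(2f₂) (or f₁(f₁−1)/2 when f₂ = 0) is the Chao1 unseen
part and (A)⁻ clamps A to [½, 1]. The multiplier 2 − (A)⁻ lies in [1, 1.5]:
Ŝ_GP is a bias-corrected Chao1 that never falls below it, equals it when the
assemblage looks homogeneous (A ≥ 1), and needs only singletons, doubletons
and tripletons — abundant species can be left uncounted in the field.

For comparison the package implements Chao1, the first-order jackknife
(S_obs + f₁), the Chao–Bunge estimator Σ_{k≥2}f_k / θ̂ with
θ̂ = 1 − f₁ΣXᵢ²/n², the negative-binomial Taylor-expansion estimator
Ŝ_LB = S_obs + (f₁²/2f₂)(3f₁f₃/2f₂²), and an experimental zero-truncated
maximum-likelihood fit. Standard errors come from the delta method under a
multinomial model for the frequency counts; confidence intervals use a
log-normal transform of Ŝ − S_obs so the lower bound never drops below the
observed richness.

A simulation harness draws multinomial samples from seven classical
species-abundance models (homogeneous, random-uniform, negative-binomial,
broken-stick, log-normal, Zipf–Mandelbrot, power-decay; CV of detection
probabilities from 0 to ~4) or from an empirical assemblage, and reports
average estimate, bias, sampling s.e., mean estimated s.e., RMSE and 95% CI
coverage per estimator.

## Worked example

```sh
python examples/estimate_richness.py
```

```
vascular plants: S_obs=188, n=1008, f1=61, f2=35, f3=18
estimator      S_hat  f0_hat    s.e.            95% CI
chao1          241.2    53.2    17.9   [ 216.0,  288.9]
jackknife1     249.0    61.0    11.0   [ 230.9,  274.7]
chao_bunge  undefined  (theta_nonpositive)
lb             259.5    71.5    49.2   [ 209.1,  430.3]
gp             254.8    66.8    35.4   [ 213.2,  365.1]
```

The packaged vascular-plant survey observed 188 species in 1,008
individuals, 61 of them exactly once. Chao1's lower bound adds 53 unseen
species; the GP estimator, seeing a doubleton ratio A ≈ 0.74 (evidence of
heterogeneity), inflates the correction by ×1.26 to 67 unseen species.
Chao–Bunge is undefined here (θ̂ ≤ 0, the classic divergence on sparse
heterogeneous data) and is reported as such rather than as a number. The
same computation is available from the shell via
`gprich estimate --input counts.csv --format frequency`.

Other examples: `gamma_poisson_model.py` (the mixture model and the moment
identity), `simulate_benchmark.py` (Monte Carlo comparison on a
Zipf–Mandelbrot assemblage), `empirical_resampling_curve.py` (bias/RMSE
versus sample size when resampling a real survey).

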