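"""Benchmark estimators on a known assemblage.

Draws repeated multinomial samples from the Zipf-Mandelbrot assemblage
(S = 1,000 species, detection probability proportional to 1/(rank+10),
CV ~ 1.88) and reports, per estimator: average estimate, bias, sampling
s.e., mean asymptotic s.e., RMSE and 95% CI coverage.  With a heavy-tailed
assemblage the nonparametric estimators underestimate at small n, while the
Gamma-Poisson estimator recovers S with near-nominal coverage.

250 replicates keep the run short; the published-style experiment uses
1,000.
"""

from gprich import make_assemblage, run_simulation, summarize

assemblage = make_assemblage("zipf_mandelbrot", S=1000)
print(f"Zipf-Mandelbrot assemblage: S=1000, CV={assemblage.cv:.2f}")
table = run_simulation(
    assemblage, n_grid=[1000, 4000], reps=250,
    estimator_ids=["chao1", "jackknife1", "lb", "gp"], seed=0,
)
print(summarize(table, "markdown"))
print("\ncoverage near 0.95 with small |bias| marks a well-calibrated "
      "estimator; true S is 1000.")
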