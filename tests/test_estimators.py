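"""Point estimators and Gamma-Poisson model functions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gprich import (
    FrequencyCounts,
    GammaPoissonParams,
    alpha_hat_moment,
    compute_estimate,
    estimate_chao1,
    estimate_chao_bunge,
    estimate_gp,
    estimate_jackknife1,
    estimate_lb,
    expected_freq_counts,
    fit_mle,
    freq_counts_from_abundances,
    gamma_poisson_pmf,
)


def expected_spectrum(S, alpha, beta, k_max=60):
    """Expected-count spectrum {k: E[f_k]} for k >= 1 as FrequencyCounts."""
    e = expected_freq_counts(S, GammaPoissonParams(alpha, beta), k_max)
    return FrequencyCounts({k: float(e[k]) for k in range(1, k_max + 1)})


class TestPmf:
    def test_alpha_one_is_geometric(self):
        p = GammaPoissonParams(1.0, 1.0)
        for k in range(6):
            assert gamma_poisson_pmf(k, p) == pytest.approx(0.5 ** (k + 1))

    def test_hand_values(self):
        p = GammaPoissonParams(2.0, 3.0)
        assert gamma_poisson_pmf(0, p) == pytest.approx(0.5625)
        assert gamma_poisson_pmf(1, p) == pytest.approx(0.28125)
        assert p.p0 == pytest.approx(0.5625)

    @pytest.mark.parametrize("alpha,beta", [(0.3, 0.5), (1, 1), (5, 0.2), (20, 40)])
    def test_normalization(self, alpha, beta):
        p = GammaPoissonParams(alpha, beta)
        # mean count alpha/beta; go far into the tail
        k_max = int(20 * (alpha / beta + 1) + 200)
        total = gamma_poisson_pmf(np.arange(k_max + 1), p).sum()
        assert total >= 1 - 1e-10

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            gamma_poisson_pmf(-1, GammaPoissonParams(1, 1))


class TestExpectedCounts:
    def test_hand_values(self):
        e = expected_freq_counts(1, GammaPoissonParams(2.0, 3.0), 3)
        assert e[1] == pytest.approx(0.28125)
        assert e[2] == pytest.approx(27 / 256)
        assert e[3] == pytest.approx(36 / 1024)

    @pytest.mark.parametrize("alpha,beta", [(0.7, 2.0), (3.0, 0.4)])
    def test_unseen_to_singleton_ratio(self, alpha, beta):
        e = expected_freq_counts(500, GammaPoissonParams(alpha, beta), 1)
        assert e[0] / e[1] == pytest.approx((beta + 1) / alpha)

    def test_large_S(self):
        e = expected_freq_counts(1000, GammaPoissonParams(1.0, 1.0), 1)
        assert e[1] == pytest.approx(250.0)


class TestAlphaHat:
    def test_vascular_row(self, vascular_fc):
        a, _ = alpha_hat_moment(vascular_fc)
        assert a == pytest.approx(1606 / 844, rel=1e-12)

    def test_equal_counts_give_one(self):
        a, _ = alpha_hat_moment(FrequencyCounts({1: 7, 2: 7, 3: 7}))
        assert a == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha", [0.2, 1.0, 2.0, 10.0, 50.0])
    @pytest.mark.parametrize("beta", [0.1, 1.0, 100.0])
    def test_moment_identity_recovers_alpha(self, alpha, beta):
        fc = expected_spectrum(1000.0, alpha, beta, k_max=3)
        a, _ = alpha_hat_moment(fc)
        assert a == pytest.approx(alpha, rel=1e-10)

    def test_zero_f3_substitution_flagged(self):
        a, diag = alpha_hat_moment(FrequencyCounts({1: 5, 2: 2}))
        assert "f3_substituted" in diag.fallbacks
        assert math.isfinite(a)

    def test_degenerate_denominator(self):
        # 3 f1 f3 == 2 f2^2: f1=2, f2=3, f3=3 -> 18 == 18
        a, diag = alpha_hat_moment(FrequencyCounts({1: 2, 2: 3, 3: 3}))
        assert math.isnan(a)
        assert "alpha_undefined" in diag.fallbacks


class TestChao1:
    def test_vascular(self, vascular_fc):
        est = estimate_chao1(vascular_fc)
        assert est.point == pytest.approx(188 + 61**2 / 70, abs=1e-9)
        assert est.point == pytest.approx(241.157, abs=1e-3)

    def test_butterfly(self, butterfly_fc):
        est = estimate_chao1(butterfly_fc)
        assert est.point == pytest.approx(620 + 118**2 / 148, abs=1e-9)
        assert est.point == pytest.approx(714.08, abs=0.01)

    def test_no_singletons(self):
        est = estimate_chao1(FrequencyCounts({2: 4, 5: 1}))
        assert est.point == 5
        assert est.f0_hat == 0

    def test_f2_zero_fallback(self):
        est = estimate_chao1(FrequencyCounts({1: 4}))
        assert est.point == 4 + 4 * 3 / 2
        assert "f2_zero_fallback" in est.diagnostics.fallbacks


class TestJackknife1:
    def test_fixtures(self, vascular_fc, butterfly_fc):
        assert estimate_jackknife1(vascular_fc).point == 188 + 61
        assert estimate_jackknife1(butterfly_fc).point == 620 + 118

    def test_no_singletons(self):
        assert estimate_jackknife1(FrequencyCounts({3: 9})).point == 9


class TestChaoBunge:
    def test_homogeneous_poisson_oracle(self):
        # Poisson(2) expectations, S=1000: f_k = 1000 e^-2 2^k / k!
        lam, S = 2.0, 1000.0
        fc = FrequencyCounts({
            k: S * math.exp(-lam) * lam**k / math.factorial(k)
            for k in range(1, 40)
        })
        assert fc.n == pytest.approx(S * lam, rel=1e-12)
        est = estimate_chao_bunge(fc)
        f1 = S * lam * math.exp(-lam)
        theta_expected = 1 - f1 * (S * (lam + lam**2)) / (S * lam) ** 2
        assert est.diagnostics.theta_hat == pytest.approx(theta_expected, rel=1e-12)
        assert est.diagnostics.theta_hat == pytest.approx(0.594, abs=0.001)
        assert est.point == pytest.approx(S, rel=1e-10)

    def test_single_abundant_species(self):
        est = estimate_chao_bunge(FrequencyCounts({7: 1}))
        assert est.diagnostics.theta_hat == 1.0
        assert est.point == 1.0

    def test_sparse_data_flagged_undefined(self):
        # f1 * sum k^2 f_k >= n^2 -> theta <= 0
        est = estimate_chao_bunge(FrequencyCounts({1: 10, 10: 1}))
        assert not est.defined
        assert "theta_nonpositive" in est.diagnostics.fallbacks


class TestLB:
    def test_vascular(self, vascular_fc):
        est = estimate_lb(vascular_fc)
        f0 = 61**2 / 70
        assert est.point == pytest.approx(188 + f0 * 3294 / 2450, abs=1e-9)
        assert est.point == pytest.approx(259.47, abs=0.01)

    def test_symmetric_counts_multiplier(self):
        est = estimate_lb(FrequencyCounts({1: 4, 2: 4, 3: 4}))
        assert est.diagnostics.multiplier == pytest.approx(1.5)

    def test_homogeneous_limit_equals_chao1(self):
        # pure-Poisson expectations satisfy 2 E[f2]^2 = 3 E[f1] E[f3]
        lam, S = 1.5, 800.0
        fc = FrequencyCounts({
            k: S * math.exp(-lam) * lam**k / math.factorial(k)
            for k in range(1, 30)
        })
        lb = estimate_lb(fc).point
        chao1 = estimate_chao1(fc).point
        assert lb == pytest.approx(chao1, rel=1e-12)


class TestGP:
    def test_vascular(self, vascular_fc):
        est = estimate_gp(vascular_fc)
        assert est.diagnostics.A == pytest.approx(2450 / 3294, rel=1e-12)
        assert est.diagnostics.multiplier == pytest.approx(2 - 2450 / 3294)
        assert est.point == pytest.approx(254.78, abs=0.01)

    def test_butterfly(self, butterfly_fc):
        est = estimate_gp(butterfly_fc)
        assert est.point == pytest.approx(742.0, abs=0.05)

    def test_clamp_at_one_equals_chao1(self):
        # 2 f2^2 >= 3 f1 f3
        fc = FrequencyCounts({1: 2, 2: 10, 3: 1})
        assert estimate_gp(fc).point == estimate_chao1(fc).point

    def test_clamp_at_half(self):
        # A < 1/2 -> multiplier exactly 1.5
        fc = FrequencyCounts({1: 20, 2: 2, 3: 20})
        est = estimate_gp(fc)
        assert est.diagnostics.A_clamped == 0.5
        assert est.diagnostics.multiplier == 1.5

    def test_homogeneous_expectations_match_chao1(self):
        lam, S = 1.5, 800.0
        fc = FrequencyCounts({
            k: S * math.exp(-lam) * lam**k / math.factorial(k)
            for k in range(1, 30)
        })
        assert estimate_gp(fc).point == pytest.approx(
            estimate_chao1(fc).point, rel=1e-9
        )

    def test_always_defined_on_degenerate_spectra(self):
        for f in ({1: 5}, {2: 3}, {3: 1}, {1: 1, 3: 1}, {4: 2}):
            est = estimate_gp(FrequencyCounts(f))
            assert est.defined
            assert est.point >= est.s_obs


counts_triples = st.tuples(
    st.integers(0, 400), st.integers(0, 400), st.integers(0, 400)
)


class TestOrderingProperties:
    @given(counts_triples)
    @settings(deadline=None, max_examples=300)
    def test_gp_between_chao1_and_lb(self, triple):
        f1, f2, f3 = triple
        fc = FrequencyCounts({1: f1, 2: f2, 3: f3, 7: 5})
        chao1 = estimate_chao1(fc).point
        gp = estimate_gp(fc)
        lb = estimate_lb(fc).point
        assert 1.0 <= gp.diagnostics.multiplier <= 1.5
        A = gp.diagnostics.A
        if A >= 1:
            assert gp.point == chao1
        else:
            assert chao1 - 1e-9 <= gp.point
            if A > 0.5 and f2 > 0:
                # unclamped region: Chao1 <= GP <= LB
                assert gp.point <= lb + 1e-9

    @given(st.lists(st.integers(1, 30), min_size=2, max_size=60))
    @settings(deadline=None, max_examples=100)
    def test_label_order_invariance(self, counts):
        fc1 = freq_counts_from_abundances(counts)
        fc2 = freq_counts_from_abundances(sorted(counts, reverse=True))
        for est_id in ("chao1", "jackknife1", "lb", "gp"):
            e1 = compute_estimate(fc1, est_id).point
            e2 = compute_estimate(fc2, est_id).point
            assert e1 == e2


class TestMLE:
    def test_parameter_recovery(self):
        # mean count alpha/beta = 4 so the truncated likelihood is well
        # identified (at mean counts < 1 the (alpha, beta) ridge is flat)
        rng = np.random.default_rng(42)
        alpha, beta, S = 2.0, 0.5, 1000
        lam = rng.gamma(alpha, 1 / beta, S)
        x = rng.poisson(lam)
        fc = freq_counts_from_abundances([int(v) for v in x[x > 0]])
        params, est = fit_mle(fc)
        assert params.alpha == pytest.approx(alpha, rel=0.2)
        assert params.beta == pytest.approx(beta, rel=0.2)
        assert est.point == pytest.approx(S, rel=0.05)

    def test_optimum_at_least_as_good_as_moment_init(self):
        rng = np.random.default_rng(7)
        lam = rng.gamma(1.0, 1.0, 400)
        x = rng.poisson(lam)
        fc = freq_counts_from_abundances([int(v) for v in x[x > 0]])
        from gprich.estimators import _truncated_negloglik, alpha_hat_moment

        params, _ = fit_mle(fc)
        a0, _ = alpha_hat_moment(fc)
        spec = fc.nonzero()
        ks = np.array(list(spec.keys()), dtype=float)
        fs = np.array(list(spec.values()), dtype=float)
        if a0 > 0:
            init = np.log([a0, a0 / (ks * fs).sum() * fs.sum()])
            at_opt = _truncated_negloglik(
                np.log([params.alpha, params.beta]), ks, fs
            )
            at_init = _truncated_negloglik(init, ks, fs)
            assert at_opt <= at_init + 1e-6

    def test_single_multiplicity_refused(self):
        with pytest.raises(ValueError):
            fit_mle(FrequencyCounts({2: 10}))
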