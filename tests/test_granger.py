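import numpy as np
import pytest
from scipy import stats

from physiocausal.granger import GrangerCausality, fit_ar, g_conditional, g_pairwise
from physiocausal.signals import (
    CommonDriverConfig,
    PairwiseSystemConfig,
    Signal,
    common_driver_system,
    fourier_filtered_noise,
    pairwise_system,
)


def normal_equations_oracle(target, blocks, p):
    """Brute-force lagged least squares via explicit normal equations.

    Independent of the package's solver: builds the design row by row and
    solves X'X beta = X'y directly.
    """
    n = len(target)
    rows = []
    for t in range(p, n):
        row = []
        for b in blocks:
            row.extend(b[t - i] for i in range(1, p + 1))
        rows.append(row)
    X = np.array(rows)
    y = np.array(target[p:])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    rss = float(np.sum((y - X @ beta) ** 2))
    return beta, rss


def oracle_g_and_f(x, extra_blocks, z, p):
    """(G, F) for the nested pair computed entirely by the oracle."""
    _, rss_r = normal_equations_oracle(x, [x] + extra_blocks, p)
    _, rss_u = normal_equations_oracle(x, [x] + extra_blocks + [z], p)
    n_obs = len(x) - p
    k_u = p * (2 + len(extra_blocks))
    g = 0.5 * np.log(rss_r / rss_u)
    f = ((rss_r - rss_u) / p) / (rss_u / (n_obs - k_u))
    return g, f


class TestFitAR:
    def test_recovers_ar1_coefficient(self):
        rng = np.random.default_rng(0)
        n = 10**5
        w = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = w[0]
        for t in range(1, n):
            x[t] = 0.5 * x[t - 1] + w[t]
        fit = fit_ar(x, p=1, labels=["x"])
        assert fit.coefficients["x"][0] == pytest.approx(0.5, abs=0.02)

    def test_white_noise_residual_std(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        fit = fit_ar(x, p=1, labels=["x"])
        assert fit.sigma == pytest.approx(x[1:].std(), rel=0.02)

    def test_alternating_series_matches_normal_equations(self):
        x = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        fit = fit_ar(x, p=1, labels=["x"])
        beta, rss = normal_equations_oracle(x, [x], 1)
        assert fit.coefficients["x"][0] == pytest.approx(beta[0], abs=1e-12)
        assert fit.rss == pytest.approx(rss, abs=1e-12)

    def test_sigma_and_nobs_convention(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        fit = fit_ar(x, p=3, labels=["x"])
        assert fit.n_obs == 97
        assert fit.sigma == pytest.approx(np.sqrt(fit.rss / fit.n_obs))

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_ar(np.arange(5.0), p=2)  # too short: need 2p+2
        with pytest.raises(ValueError):
            fit_ar(np.arange(10.0), [np.arange(8.0)], p=1)
        with pytest.raises(ValueError):
            fit_ar(np.arange(10.0), p=0)

    def test_collinear_design_is_flagged(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        fit = fit_ar(x, [x], p=2, labels=["x", "copy"])  # duplicated block
        assert fit.collinear


class TestOracleEquivalence:
    @pytest.mark.parametrize("n,p,seed", [(20, 1, 0), (50, 2, 1), (31, 2, 2), (50, 1, 3)])
    def test_pairwise_matches_normal_equations(self, n, p, seed):
        rng = np.random.default_rng(seed)
        x, z = rng.standard_normal((2, n))
        res = g_pairwise(x, z, p=p)
        g, f = oracle_g_and_f(x, [], z, p)
        assert res.g_value == pytest.approx(g, abs=1e-8)
        assert res.statistic == pytest.approx(f, abs=1e-8)

    @pytest.mark.parametrize("n,p,seed", [(30, 1, 4), (50, 2, 5)])
    def test_conditional_matches_normal_equations(self, n, p, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.standard_normal((3, n))
        res = g_conditional(x, z, [y], p=p)
        g, f = oracle_g_and_f(x, [y], z, p)
        assert res.g_value == pytest.approx(g, abs=1e-8)
        assert res.statistic == pytest.approx(f, abs=1e-8)
        assert res.df == (p, (n - p) - 3 * p)


class TestNestingProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_g_nonnegative_and_rss_monotone(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.standard_normal((3, 120))
        res = g_conditional(x, z, [y], p=4)
        assert res.g_value >= 0.0
        assert res.unrestricted.rss <= res.restricted.rss + 1e-9
        assert res.unrestricted.sigma <= res.restricted.sigma + 1e-12

    def test_perfect_fit_sentinel(self):
        z, x = pairwise_system(PairwiseSystemConfig(n=500, q=1.0, seed=6))
        res = g_pairwise(x, z, p=5)
        assert np.isinf(res.g_value) and res.p_value == 0.0

    def test_constant_target_degenerate(self):
        x = np.zeros(60)
        z = np.random.default_rng(7).standard_normal(60)
        res = g_pairwise(x, z, p=2)
        assert res.p_value == 1.0 and res.g_value == 0.0


class TestSignificance:
    def test_type_one_error_near_nominal(self):
        # independent white-noise pairs; binomial CI around 0.05
        rej = 0
        reps = 300
        rng = np.random.default_rng(8)
        for _ in range(reps):
            x, z = rng.standard_normal((2, 256))
            rej += g_pairwise(x, z, p=3).p_value < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.03)

    def test_detects_moderate_coupling(self):
        hits = 0
        for seed in range(20):
            z, x = pairwise_system(PairwiseSystemConfig(n=2**12, q=0.5, seed=seed))
            hits += g_pairwise(x, z, p=5).p_value < 0.05
        assert hits >= 19

    def test_chi2_variant_consistent(self):
        z, x = pairwise_system(PairwiseSystemConfig(n=1024, q=0.3, seed=9))
        f_res = g_pairwise(x, z, p=5, test="f")
        c_res = g_pairwise(x, z, p=5, test="chi2")
        assert c_res.statistic == pytest.approx(5 * f_res.statistic)
        assert c_res.p_value == pytest.approx(float(stats.chi2.sf(c_res.statistic, 5)))
        with pytest.raises(ValueError):
            GrangerCausality(x, z).fit(test="bogus")


class TestConditionalAnalysis:
    def test_common_driver_pairwise_rejects_conditional_does_not(self):
        # indirect-link regime: moderate couplings through a hidden driver
        pair_rej = cond_rej = 0
        for seed in range(20):
            x, y, z = common_driver_system(
                CommonDriverConfig(n=2**15, q_yz=0.15, q_yx=0.15, seed=seed)
            )
            pair_rej += g_pairwise(x, z, p=5).p_value < 0.05
            cond_rej += g_conditional(x, z, [y], p=5).p_value < 0.05
        assert pair_rej > 10
        assert cond_rej <= 10

    def test_null_conditional_rejection_near_nominal(self):
        rej = 0
        reps = 200
        rng = np.random.default_rng(10)
        for _ in range(reps):
            x, y, z = rng.standard_normal((3, 256))
            rej += g_conditional(x, z, [y], p=3).p_value < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.04)

    def test_irrelevant_conditioning_changes_little(self):
        # conditioning on an unrelated signal leaves G essentially unchanged
        ratios = []
        for seed in range(20):
            z, x = pairwise_system(PairwiseSystemConfig(n=2**12, q=0.5, seed=seed))
            y = fourier_filtered_noise(x.n, 0.5, seed=1000 + seed)
            g_p = g_pairwise(x, z, p=5).g_value
            g_c = g_conditional(x, z, [y], p=5).g_value
            ratios.append(g_c / g_p)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)

    def test_requires_conditioning_series(self):
        rng = np.random.default_rng(11)
        x, z = rng.standard_normal((2, 100))
        with pytest.raises(ValueError):
            g_conditional(x, z, [], p=2)


def test_summary_mentions_key_quantities():
    z, x = pairwise_system(PairwiseSystemConfig(n=512, q=0.5, seed=12))
    text = GrangerCausality(x, z, order=5).fit().summary()
    assert "G-value" in text and "p-value" in text and "z -> x" in text


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), p=st.integers(1, 3))
def test_g_nonnegativity_property(seed, p):
    # nested least squares on identical rows: restricted RSS >= unrestricted
    rng = np.random.default_rng(seed)
    x, z = rng.standard_normal((2, 60))
    res = g_pairwise(x, z, p=p)
    assert res.g_value >= 0.0
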