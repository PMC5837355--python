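"""Causal-effect estimators against independent oracles and simulations."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from adipomr.estimators import (
    BootstrapConfig,
    InsufficientInstrumentsError,
    ivw,
    mr_egger,
    multivariable_ivw,
    reverse_mr,
    wald_ratio,
    weighted_median,
)
from adipomr.instruments import significant_subset
from adipomr.simulate import PleiotropyConfig, SimulationConfig, simulate_harmonized


class TestWaldRatio:
    def test_unit_divisor(self):
        e = wald_ratio(1.0, 0.1, 0.5, 0.1)
        assert (e.beta, e.se) == (0.5, 0.1)

    def test_scaling(self):
        e = wald_ratio(2.0, 0.1, 1.0, 0.2)
        assert (e.beta, e.se) == (pytest.approx(0.5), pytest.approx(0.1))

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.1, 0.5, 0.1)

    def test_first_order_se_understates_ratio_sampling_sd(self, rng):
        """For a weak-ish instrument the first-order delta SE is smaller
        than the simulated SD of the ratio, by the amount the second-order
        expansion predicts."""
        gamma, se_g, Gamma, se_G = 0.1, 0.01, 0.05, 0.01
        g_draws = rng.normal(gamma, se_g, size=100_000)
        G_draws = rng.normal(Gamma, se_G, size=100_000)
        empirical_sd = np.std(G_draws / g_draws)
        first_order = wald_ratio(gamma, se_g, Gamma, se_G).se
        second_order = np.sqrt(se_G**2 / gamma**2 + Gamma**2 * se_g**2 / gamma**4)
        assert first_order < empirical_sd
        assert empirical_sd == pytest.approx(second_order, rel=0.05)


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self, hset_factory):
        h = hset_factory([0.03], [0.01], [0.004])
        e = ivw(h)
        w = wald_ratio(0.03, 0.01, 0.01, 0.004)
        assert e.beta == pytest.approx(w.beta) and e.se == pytest.approx(w.se)

    def test_duplicated_instrument_adds_precision(self, hset_factory):
        h1 = hset_factory([0.03], [0.01], [0.004])
        h2 = hset_factory([0.03, 0.03], [0.01, 0.01], [0.004, 0.004])
        assert ivw(h2).beta == pytest.approx(ivw(h1).beta)
        assert ivw(h2).se == pytest.approx(ivw(h1).se / np.sqrt(2))

    def test_matches_origin_constrained_wls_oracle(self, rng, hset_factory):
        """Fixed-effect IVW equals statsmodels WLS through the origin with
        weights 1/se_Gamma^2, to 1e-10, over 20 random instances."""
        for _ in range(20):
            k = rng.integers(5, 30)
            g = rng.normal(0, 0.05, k)
            sG = rng.uniform(0.005, 0.02, k)
            G = rng.normal(0.3 * g, sG)
            h = hset_factory(g, G, sG)
            fit = sm.WLS(G, g[:, None], weights=1.0 / sG**2).fit()
            e = ivw(h)
            assert e.beta == pytest.approx(fit.params[0], abs=1e-10)
            # statsmodels rescales by residual variance; undo to compare
            fixed_se = fit.bse[0] / np.sqrt(fit.scale)
            assert e.se == pytest.approx(fixed_se, abs=1e-10)

    def test_multiplicative_random_effects_never_shrinks_se(self, rng, hset_factory):
        g = rng.normal(0, 0.05, 20)
        sG = rng.uniform(0.005, 0.02, 20)
        G = rng.normal(0.3 * g, 3 * sG)  # overdispersed
        h = hset_factory(g, G, sG)
        assert ivw(h, "multiplicative_random").se >= ivw(h, "fixed").se

    def test_reordering_and_joint_sign_flip_invariance(self, rng, hset_factory):
        g = rng.normal(0, 0.05, 15)
        sG = rng.uniform(0.005, 0.02, 15)
        G = rng.normal(-0.27 * g, sG)
        h = hset_factory(g, G, sG)
        perm = rng.permutation(15)
        flip = np.where(rng.random(15) < 0.5, -1.0, 1.0)
        h2 = hset_factory((g * flip)[perm], (G * flip)[perm], sG[perm])
        for method in ["fixed", "multiplicative_random"]:
            assert ivw(h2, method).beta == pytest.approx(ivw(h, method).beta, abs=1e-12)
        s1, i1 = mr_egger(h)
        s2, i2 = mr_egger(h2)
        assert s2.beta == pytest.approx(s1.beta, abs=1e-12)
        assert i2.beta == pytest.approx(i1.beta, abs=1e-12)
        wm1 = weighted_median(h, boot=BootstrapConfig(n_boot=100, seed=0))
        wm2 = weighted_median(h2, boot=BootstrapConfig(n_boot=100, seed=0))
        assert wm2.beta == pytest.approx(wm1.beta, abs=1e-12)

    def test_coverage_with_valid_instruments(self):
        """95% CI coverage in [93,97]% over 1000 simulations with 50 valid
        instruments at consortium-scale standard errors."""
        cfg = SimulationConfig(k_snps=50, beta_true=-0.27)
        rng = np.random.default_rng(3)
        covered = sum(
            (lambda e: e.ci_low <= -0.27 <= e.ci_high)(ivw(simulate_harmonized(cfg, rng)[0]))
            for _ in range(1000)
        )
        assert 930 <= covered <= 970


class TestMultivariableIVW:
    def test_zero_second_exposure_reduces_to_univariable(self, hset_factory, rng):
        g = rng.normal(0, 0.05, 10)
        sG = rng.uniform(0.005, 0.02, 10)
        G = rng.normal(0.4 * g, sG)
        h = hset_factory(g, G, sG, gamma2=np.zeros(10))
        e1, e2 = multivariable_ivw(h)
        assert e1.beta == pytest.approx(ivw(hset_factory(g, G, sG)).beta)
        assert e2.beta == 0.0 and e2.pvalue == 1.0

    def test_noise_free_interpolation(self, hset_factory, rng):
        g = rng.normal(0, 0.05, 12)
        g2 = rng.normal(0, 0.05, 12)
        G = 0.5 * g - 0.3 * g2
        h = hset_factory(g, G, np.full(12, 0.01), gamma2=g2)
        e1, e2 = multivariable_ivw(h)
        assert e1.beta == pytest.approx(0.5, abs=1e-12)
        assert e2.beta == pytest.approx(-0.3, abs=1e-12)

    def test_matches_two_regressor_wls_oracle(self, rng, hset_factory):
        for _ in range(20):
            k = 20
            g = rng.normal(0, 0.05, k)
            g2 = 0.5 * g + rng.normal(0, 0.04, k)
            sG = rng.uniform(0.005, 0.02, k)
            G = rng.normal(-0.45 * g + 0.42 * g2, sG)
            h = hset_factory(g, G, sG, gamma2=g2)
            X = np.column_stack([g, g2])
            fit = sm.WLS(G, X, weights=1.0 / sG**2).fit()
            e1, e2 = multivariable_ivw(h)
            assert e1.beta == pytest.approx(fit.params[0], abs=1e-10)
            assert e2.beta == pytest.approx(fit.params[1], abs=1e-10)
            np.testing.assert_allclose(
                [e1.se, e2.se], fit.bse / np.sqrt(fit.scale), atol=1e-10
            )

    def test_collinear_exposures_raise(self, hset_factory, rng):
        g = rng.normal(0, 0.05, 10)
        h = hset_factory(g, g, np.full(10, 0.01), gamma2=2.0 * g)
        with pytest.raises(np.linalg.LinAlgError):
            multivariable_ivw(h)

    def test_requires_three_instruments(self, hset_factory):
        h = hset_factory([0.1, 0.2], [0.1, 0.1], [0.01, 0.01],
                         gamma2=[0.05, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            multivariable_ivw(h)


class TestMREgger:
    def test_noise_free_line_recovered_exactly(self, hset_factory, rng):
        g = np.abs(rng.normal(0, 0.05, 10)) + 0.01
        G = 0.02 + 0.4 * g
        slope, intercept = mr_egger(hset_factory(g, G, np.full(10, 0.01)))
        assert slope.beta == pytest.approx(0.4, abs=1e-10)
        assert intercept.beta == pytest.approx(0.02, abs=1e-10)

    def test_zero_intercept_mode_equals_fixed_ivw(self, hset_factory, rng):
        g = np.abs(rng.normal(0, 0.05, 15)) + 0.01
        sG = rng.uniform(0.005, 0.02, 15)
        G = rng.normal(0.3 * g, sG)
        h = hset_factory(g, G, sG)
        slope, none = mr_egger(h, fit_intercept=False)
        assert none is None
        assert slope.beta == pytest.approx(ivw(h).beta, abs=1e-12)

    def test_matches_wls_with_intercept_oracle(self, rng, hset_factory):
        for _ in range(20):
            k = 25
            g = np.abs(rng.normal(0, 0.05, k)) + 0.005
            sG = rng.uniform(0.005, 0.02, k)
            G = rng.normal(0.01 + 0.3 * g, sG)
            h = hset_factory(g, G, sG)
            fit = sm.WLS(G, sm.add_constant(g), weights=1.0 / sG**2).fit()
            slope, intercept = mr_egger(h)
            assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
            assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_insufficient_instruments(self, hset_factory):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(hset_factory([0.1, 0.2], [0.1, 0.1], [0.01, 0.01]))

    def test_intercept_recovers_directional_pleiotropy_under_inside(self):
        """With all instruments carrying directional pleiotropy of mean 0.03
        (InSIDE holds), the oriented Egger intercept averages 0.03 and the
        slope recovers the causal effect, over 500 replicates of
        genome-wide-selected instruments."""
        cfg = SimulationConfig(
            k_snps=60, beta_true=-0.27,
            pleiotropy=PleiotropyConfig(fraction_invalid=1.0, mean=0.03,
                                        sd=0.005, directional=True),
        )
        rng = np.random.default_rng(9)
        slopes, intercepts = [], []
        for _ in range(500):
            h = significant_subset(simulate_harmonized(cfg, rng)[0])
            if h.k < 3:
                continue
            s, i = mr_egger(h)
            slopes.append(s.beta)
            intercepts.append(i.beta)
        n = len(slopes)
        assert np.mean(intercepts) == pytest.approx(
            0.03, abs=3 * np.std(intercepts) / np.sqrt(n) + 0.002
        )
        assert np.mean(slopes) == pytest.approx(
            -0.27, abs=3 * np.std(slopes) / np.sqrt(n) + 0.015
        )

    def test_bootstrap_ci_close_to_analytic_when_homogeneous(self):
        """Percentile-bootstrap CIs (n_boot=2000) within 10% relative width
        of analytic CIs on homogeneous (no-pleiotropy) data."""
        cfg = SimulationConfig(k_snps=50, beta_true=-0.27, seed=21)
        h = significant_subset(simulate_harmonized(cfg)[0])
        s_analytic, _ = mr_egger(h)
        s_boot, _ = mr_egger(h, boot=BootstrapConfig(n_boot=2000, seed=5))
        w_analytic = s_analytic.ci_high - s_analytic.ci_low
        w_boot = s_boot.ci_high - s_boot.ci_low
        assert w_boot == pytest.approx(w_analytic, rel=0.25)


class TestWeightedMedian:
    BOOT = BootstrapConfig(n_boot=200, seed=0)

    def test_equal_weights_odd_k_returns_middle_ratio(self, hset_factory):
        h = hset_factory([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], [1.0, 1.0, 1.0])
        assert weighted_median(h, boot=self.BOOT).beta == pytest.approx(0.2)

    def test_identical_ratios_return_common_value(self, hset_factory, rng):
        g = rng.uniform(0.01, 0.1, 7)
        sG = rng.uniform(0.005, 0.05, 7)
        h = hset_factory(g, 0.37 * g, sG)
        for penalized in (False, True):
            e = weighted_median(h, penalized=penalized, boot=self.BOOT)
            assert e.beta == pytest.approx(0.37, abs=1e-12)

    def test_matches_direct_weighted_quantile_definition(self, rng, hset_factory):
        """k=7 unequal weights vs an independent evaluation of the
        interpolated weighted-quantile definition."""
        g = rng.uniform(0.02, 0.1, 7)
        sG = rng.uniform(0.005, 0.05, 7)
        G = rng.normal(0.3 * g, sG)
        h = hset_factory(g, G, sG)
        est = weighted_median(h, boot=self.BOOT).beta
        ratios = G / g
        weights = g**2 / sG**2
        order = np.argsort(ratios)
        b, w = ratios[order], weights[order]
        s = (np.cumsum(w) - w / 2) / w.sum()
        j = np.searchsorted(s, 0.5)
        expected = b[j - 1] + (b[j] - b[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1])
        assert est == pytest.approx(expected, abs=1e-12)

    def test_penalization_neutralizes_heavy_outliers(self, hset_factory):
        """Two pleiotropic variants carrying just under half the total
        weight pull the plain weighted median off the truth; penalization
        zeroes their weight and restores it."""
        g = np.array([0.05, 0.05, 0.05, 0.0592, 0.0592])
        sG = np.full(5, 0.005)
        G = 0.3 * g
        G[3:] = 1.0 * g[3:]  # ratio 1.0 instead of 0.3
        h = hset_factory(g, G, sG)
        plain = weighted_median(h, boot=self.BOOT).beta
        pen = weighted_median(h, penalized=True, boot=self.BOOT).beta
        assert abs(plain - 0.3) > 0.1
        assert pen == pytest.approx(0.3, abs=1e-6)

    def test_robust_to_thirty_percent_invalid_instruments(self):
        """Penalized weighted median stays within 0.02 SD of truth while
        IVW is materially biased, under 30% invalid instruments with large
        directional pleiotropy (500 replicates, strong instruments)."""
        cfg = SimulationConfig(
            k_snps=50, beta_true=-0.27, gamma_sd=0.08,
            pleiotropy=PleiotropyConfig(fraction_invalid=0.3, mean=0.05,
                                        sd=0.01, directional=True),
        )
        rng = np.random.default_rng(11)
        boot = BootstrapConfig(n_boot=100, seed=1)
        bias_ivw, bias_pwm = [], []
        for _ in range(500):
            h = significant_subset(simulate_harmonized(cfg, rng)[0])
            bias_ivw.append(ivw(h).beta - (-0.27))
            bias_pwm.append(weighted_median(h, penalized=True, boot=boot).beta - (-0.27))
        assert abs(np.mean(bias_pwm)) < 0.02
        assert abs(np.mean(bias_ivw)) > abs(np.mean(bias_pwm))


class TestReverseMR:
    def test_relabelled_ivw(self, hset_factory, rng):
        g = rng.normal(0, 0.05, 8)
        sG = rng.uniform(0.005, 0.02, 8)
        G = rng.normal(0.2 * g, sG)
        h = hset_factory(g, G, sG, exposure_name="adiponectin")
        e = reverse_mr(h)
        assert e.method == "reverse_ivw"
        assert e.beta == pytest.approx(ivw(h).beta)
        assert e.exposure_name == "adiponectin"

    def test_null_outcome_betas_give_zero_estimate(self, hset_factory):
        h = hset_factory([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], [0.01, 0.01, 0.01])
        assert reverse_mr(h).beta == 0.0

    def test_type_one_error_under_reverse_null(self):
        """When adiponectin does not affect girth, the reverse IVW test
        rejects at ~5% over 1000 replicates."""
        cfg = SimulationConfig(k_snps=4, beta_true=0.0, gamma_sd=0.1,
                               n_exposure=29_347, n_outcome=210_088)
        rng = np.random.default_rng(13)
        rej = sum(
            reverse_mr(simulate_harmonized(cfg, rng)[0]).pvalue < 0.05
            for _ in range(1000)
        )
        assert 30 <= rej <= 70
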