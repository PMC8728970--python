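"""Analytic power engine: Welch, legacy, paired, SESOI and TOST variants."""

import math

import numpy as np
import pytest
from scipy import stats

from cytopower import (
    GroupSpec,
    TestSpec,
    apply_sesoi,
    fnr,
    fnr_legacy,
    fnr_paired,
    fnr_unpaired,
    paired_cov,
    tost_power,
    welch_df,
)
from cytopower.power import observed_correlation
from cytopower.simulate import SimConfig, empirical_fnr


class TestWelchDf:
    def test_equal_variances_and_sizes_give_student_df(self):
        for M in (2, 5, 12):
            assert welch_df(0.004, 0.004, M, M) == pytest.approx(2 * M - 2, rel=1e-12)

    def test_hand_value(self):
        assert welch_df(0.002648, 0.002702, 6, 6) == pytest.approx(9.999, abs=2e-3)

    def test_dominated_variance_limit(self):
        # one group's variance term dwarfs the other: df drops toward m-1
        assert welch_df(1e-12, 1.0, 50, 2) == pytest.approx(1.0, abs=1e-6)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_df(0.01, 0.01, 1, 5)


class TestUnpaired:
    def test_clinical_trial_cell(self, trial_arms, one_sided):
        # 18.6% -> 28.6%, 6+6 samples, 1000 cells: beta clears the 0.1 bar
        g0, g1 = trial_arms
        for mode in ("shifted_central_t", "noncentral_t"):
            t = TestSpec(cdf_mode=mode)
            res = fnr_unpaired(g0, g1, t)
            assert 0.05 <= res.beta <= 0.09
            assert res.beta <= 0.1

    def test_equal_means_one_sided_beta_is_complement_of_alpha(self, one_sided):
        g = GroupSpec(m=5, n=500, mu=0.2, sigma=0.05)
        res = fnr_unpaired(g, g, one_sided)
        assert res.beta == pytest.approx(1 - one_sided.alpha, abs=1e-12)

    def test_result_invariants(self, trial_arms, one_sided):
        res = fnr_unpaired(*trial_arms, one_sided)
        assert res.beta + res.power == pytest.approx(1.0, abs=1e-15)
        assert 0 < res.beta < 1

    def test_two_sided_beta_not_smaller(self, trial_arms):
        one = fnr_unpaired(*trial_arms, TestSpec(sides="one_sided"))
        two = fnr_unpaired(*trial_arms, TestSpec(sides="two_sided"))
        assert two.beta >= one.beta

    def test_wrong_direction_warns(self, one_sided):
        g0 = GroupSpec(m=6, n=1000, mu=0.3, sigma=0.05)
        g1 = GroupSpec(m=6, n=1000, mu=0.2, sigma=0.05)
        with pytest.warns(UserWarning, match="direction"):
            res = fnr_unpaired(g0, g1, one_sided)
        assert res.beta > 1 - one_sided.alpha

    @pytest.mark.parametrize(
        "mu0, mu1, n, m",
        [(0.10, 0.15, 1000, 8), (0.20, 0.30, 1000, 8), (0.05, 0.075, 384, 10)],
    )
    def test_matches_monte_carlo(self, mu0, mu1, n, m):
        """Analytic beta tracks the simulated false-negative rate."""
        g0 = GroupSpec(m=m, n=n, mu=mu0, sigma=0.3 * mu0)
        g1 = GroupSpec(m=m, n=n, mu=mu1, sigma=0.3 * mu1)
        res = empirical_fnr(SimConfig(g0, g1, TestSpec(), replicates=20_000, seed=0))
        assert abs(res.empirical_fnr - res.analytic_fnr) < 0.02


class TestLegacy:
    def test_equals_unpaired_at_enormous_cell_count(self, one_sided):
        g0 = GroupSpec(m=8, n=10**9, mu=0.03, sigma=0.015)
        g1 = GroupSpec(m=8, n=10**9, mu=0.05, sigma=0.01)
        full = fnr_unpaired(g0, g1, one_sided).beta
        legacy = fnr_legacy(0.03, 0.015, 8, 0.05, 0.01, 8, one_sided).beta
        assert abs(full - legacy) < 1e-6

    def test_more_optimistic_than_finite_cells(self, rare_arms, one_sided):
        full = fnr_unpaired(*rare_arms, one_sided).beta
        legacy = fnr_legacy(0.03, 0.015, 8, 0.05, 0.01, 8, one_sided).beta
        assert legacy < full

    def test_equal_means_beta_is_complement_of_alpha(self, one_sided):
        res = fnr_legacy(0.2, 0.05, 6, 0.2, 0.05, 6, one_sided)
        assert res.beta == pytest.approx(0.95, abs=1e-12)


class TestPaired:
    @staticmethod
    def arms(m=10, n=1000):
        return (
            GroupSpec(m=m, n=n, mu=0.10, sigma=0.03),
            GroupSpec(m=m, n=n, mu=0.14, sigma=0.03),
        )

    def test_covariance_zero_at_rho_zero_and_linear(self):
        g0, g1 = self.arms()
        assert paired_cov(g0, g1, 0.0) == 0.0
        c1 = paired_cov(g0, g1, 0.79)
        assert c1 == pytest.approx(0.79 * g0.sigma * g1.sigma, rel=1e-9)
        assert paired_cov(g0, g1, 0.395) == pytest.approx(c1 / 2, rel=1e-12)

    def test_observed_correlation_attenuated(self):
        # at rho=1 the observed proportions correlate by n/(a+b+n) < 1
        g = GroupSpec(m=10, n=1000, mu=0.2, sigma=0.05)
        r = observed_correlation(g, g, 1.0)
        assert r == pytest.approx(g.n / (g.a + g.b + g.n), rel=1e-12)
        assert r < 1.0

    def test_rho_zero_ncp_matches_unpaired_exactly(self):
        g0, g1 = self.arms()
        paired = fnr_paired(g0, g1, TestSpec(design="paired", rho=0.0))
        unpaired = fnr_unpaired(g0, g1, TestSpec())
        assert paired.ncp == pytest.approx(unpaired.ncp, rel=1e-14)
        assert paired.df == g0.m - 1
        # beta differs only through the degrees of freedom (M-1 vs 2M-2)
        assert paired.beta > unpaired.beta

    def test_beta_strictly_decreases_in_rho(self):
        g0, g1 = self.arms()
        betas = [
            fnr_paired(g0, g1, TestSpec(design="paired", rho=r)).beta
            for r in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(b0 > b1 for b0, b1 in zip(betas, betas[1:]))

    def test_negative_rho_warns(self):
        g0, g1 = self.arms()
        with pytest.warns(UserWarning, match="negative rho"):
            fnr_paired(g0, g1, TestSpec(design="paired", rho=-0.5))

    def test_unequal_sizes_rejected(self):
        g0, _ = self.arms(m=10)
        _, g1 = self.arms(m=8)
        with pytest.raises(ValueError, match="equal group sizes"):
            fnr_paired(g0, g1, TestSpec(design="paired", rho=0.5))

    def test_matches_monte_carlo(self):
        g0, g1 = self.arms()
        t = TestSpec(design="paired", rho=0.9)
        res = empirical_fnr(SimConfig(g0, g1, t, replicates=20_000, seed=0))
        assert abs(res.empirical_fnr - res.analytic_fnr) < 0.02

    def test_rho_only_for_paired(self):
        with pytest.raises(ValueError, match="paired"):
            TestSpec(design="unpaired", rho=0.5)


class TestSesoi:
    def test_zero_margin_is_identity(self):
        g = GroupSpec(m=6, n=1000, mu=0.186, sigma=0.05)
        assert apply_sesoi(g, 0.0) is g

    def test_shift_arithmetic(self):
        g = GroupSpec(m=6, n=1000, mu=0.186, sigma=0.05)
        assert apply_sesoi(g, 0.05, "add").mu == pytest.approx(0.236)
        assert apply_sesoi(g, 0.05, "subtract").mu == pytest.approx(0.136)

    def test_shift_leaving_unit_interval_rejected(self):
        g = GroupSpec(m=6, n=1000, mu=0.99, sigma=0.002)
        with pytest.raises(ValueError, match="leaves"):
            apply_sesoi(g, 0.05, "add")

    def test_dispatch_applies_margin_toward_case(self, one_sided):
        g0 = GroupSpec(m=6, n=1000, mu=0.186, sigma=0.05)
        g1 = GroupSpec(m=6, n=1000, mu=0.286, sigma=0.05)
        with_margin = fnr(g0, g1, TestSpec(sesoi=0.05))
        explicit = fnr_unpaired(apply_sesoi(g0, 0.05, "add"), g1, one_sided)
        assert with_margin.beta == pytest.approx(explicit.beta, rel=1e-12)
        # demanding a 5-point margin on top of the effect costs power
        assert with_margin.beta > fnr(g0, g1, TestSpec()).beta


class TestTost:
    def test_equal_means_large_margin_high_power(self):
        g = GroupSpec(m=40, n=1000, mu=0.2, sigma=0.05)
        res = tost_power(g, g, margin=0.1, t=TestSpec())
        assert res.power > 0.99

    def test_tiny_margin_no_power(self):
        g = GroupSpec(m=10, n=1000, mu=0.2, sigma=0.05)
        res = tost_power(g, g, margin=1e-4, t=TestSpec())
        assert res.power < 0.01

    def test_true_difference_at_margin_no_power(self):
        g0 = GroupSpec(m=20, n=1000, mu=0.2, sigma=0.05)
        g1 = GroupSpec(m=20, n=1000, mu=0.35, sigma=0.05)
        res = tost_power(g0, g1, margin=0.05, t=TestSpec())
        assert res.power < 0.05

    def test_nonpositive_margin_rejected(self):
        g = GroupSpec(m=10, n=1000, mu=0.2, sigma=0.05)
        with pytest.raises(ValueError):
            tost_power(g, g, margin=0.0, t=TestSpec())

    def test_matches_monte_carlo(self):
        """Equivalence power against a simulated two one-sided procedure."""
        g = GroupSpec(m=20, n=1000, mu=0.2, sigma=0.05)
        analytic = tost_power(g, g, margin=0.1, t=TestSpec()).power
        rng = np.random.default_rng(11)
        reps, M = 20_000, 20
        p0 = rng.beta(g.a, g.b, (reps, M))
        p1 = rng.beta(g.a, g.b, (reps, M))
        x0 = rng.binomial(g.n, p0) / g.n
        x1 = rng.binomial(g.n, p1) / g.n
        v0, v1 = x0.var(1, ddof=1), x1.var(1, ddof=1)
        w0, w1 = v0 / M, v1 / M
        se = np.sqrt(w0 + w1)
        df = (w0 + w1) ** 2 / (w0**2 / (M - 1) + w1**2 / (M - 1))
        crit = stats.t.ppf(0.95, df)
        d = x1.mean(1) - x0.mean(1)
        both = ((d + 0.1) / se > crit) & ((d - 0.1) / se < -crit)
        assert abs(analytic - both.mean()) < 0.03


class TestMonotonicity:
    def test_beta_non_increasing_in_samples_and_cells(self):
        """More samples or more cells never hurts power (seeded sweep)."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            mu0 = rng.uniform(0.02, 0.5)
            mu1 = mu0 * rng.uniform(1.2, 2.0)
            if not mu1 < 0.95:
                continue
            try:
                g0 = GroupSpec(m=4, n=200, mu=mu0, sigma=0.25 * mu0)
                g1 = GroupSpec(m=4, n=200, mu=mu1, sigma=0.25 * mu1)
            except ValueError:
                continue
            t = TestSpec()
            b_m = [fnr(g0.with_m(m), g1.with_m(m), t).beta for m in (4, 8, 16)]
            assert b_m[0] >= b_m[1] >= b_m[2]
            b_n = [
                fnr(g0.with_n(n), g1.with_n(n), t).beta for n in (100, 400, 1600)
            ]
            assert b_n[0] >= b_n[1] >= b_n[2]
            checked += 1
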