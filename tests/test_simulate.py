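"""Synthetic-data generator: distributional checks and closed-form oracles."""

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import kstest

from markqr.data import MarkQRError
from markqr.simulate import (
    CALIBRATED_CENSORING_MEANS,
    SimulationDesign,
    ToyOracle,
    calibrate_censoring,
    design,
    generate,
    generate_toy,
    true_beta,
    true_cqve,
    true_qve,
)


class TestGenerator:
    def test_covariate_marginals(self):
        data = generate(design("M1", n=100_000), seed=2)
        z1, z2 = data.covariates[:, 0], data.covariates[:, 1]
        assert z1.mean() == pytest.approx(0.5, abs=0.01)
        assert kstest(z2, "uniform").statistic < 0.01
        # positive dependence from the 0.5 latent correlation
        assert np.corrcoef(z1, z2)[0, 1] > 0.3

    def test_treated_arm_mark_density_is_2v(self):
        data = generate(design("M3", n=100_000), seed=3)
        # all marks (latent ones included) are only kept at events; restrict
        # to treated events and compare the empirical CDF with v²
        treated_ev = (data.status == 1.0) & (data.covariates[:, 0] == 1.0)
        v = data.mark[treated_ev]
        assert v.size > 10_000
        # censoring is mark-dependent only through T; KS against the
        # observed-arm approximation stays loose
        grid = np.linspace(0.05, 0.95, 19)
        ecdf = np.searchsorted(np.sort(v), grid) / v.size
        assert np.abs(ecdf - grid**2).max() < 0.05

    def test_treated_latent_mean_mark(self):
        des = design("M4", n=200_000)
        from markqr.simulate import _draw_failures

        rng = np.random.default_rng(11)
        Z1, Z2, V, T = _draw_failures(des, des.n, rng)
        treated = Z1 == 1.0
        assert V[treated].mean() == pytest.approx(2.0 / 3.0, abs=0.005)
        assert V[~treated].mean() == pytest.approx(0.5, abs=0.005)

    def test_determinism_under_fixed_seed(self):
        d1 = generate(design("M2", n=500), seed=9)
        d2 = generate(design("M2", n=500), seed=9)
        np.testing.assert_array_equal(d1.time, d2.time)
        np.testing.assert_array_equal(d1.status, d2.status)

    def test_design_parameter_consistency_enforced(self):
        with pytest.raises(MarkQRError):
            SimulationDesign(model="M3", mu=0.0, gamma11=0.0, gamma12=0.0)


class TestTrueCoefficients:
    def test_m3_treatment_effect_flat_at_half(self):
        # at v = 1/2 the density factor is 1, so β1 reduces to γ11 = 0.43
        des = design("M3")
        for tau in (0.1, 0.2, 0.3, 0.4):
            assert true_beta(des, 0.5, tau)[1] == pytest.approx(0.43, abs=1e-15)

    def test_median_intercept_is_zero(self):
        assert true_beta(design("M1"), 0.6, 0.5)[0] == pytest.approx(0.0)

    def test_baseline_covariate_coefficient(self):
        # γ2(0.6) = 0.5(1 + 0.36)
        assert true_beta(design("M2"), 0.6, 0.2)[2] == pytest.approx(0.68)

    def test_domain_error_when_treated_quantile_undefined(self):
        with pytest.raises(MarkQRError):
            true_beta(design("M4"), v=0.2, tau=0.45)

    def test_m1_truth_is_no_efficacy(self):
        des = design("M1")
        assert true_qve(des, 0.55, 0.25) == 0.0
        assert true_cqve(des, 0.7, 0.25) == 0.0

    def test_quantile_identity_against_conditional_law(self):
        """Plugging β*(v,τ) into the model reproduces the mark-specific
        incidence level τ: F_v(Q) = f_V(v|Z̃1) Φ(log Q − γ(v)'Z̃) = τ."""
        from scipy.special import ndtr

        des = design("M4")
        for v, tau, z in [(0.4, 0.2, (1.0, 0.3)), (0.7, 0.35, (1.0, 0.9)),
                          (0.5, 0.15, (0.0, 0.5))]:
            beta = true_beta(des, v, tau)
            logq = beta @ np.array([1.0, *z])
            dens = 2.0 * v if z[0] == 1.0 else 1.0
            gamma_z = des.gamma1(v) * z[0] + des.gamma2(v) * z[1]
            assert dens * ndtr(logq - gamma_z) == pytest.approx(tau, abs=1e-12)


class TestCensoringCalibration:
    def test_cached_means_hit_forty_percent(self):
        for m in ("M1", "M2"):
            data = generate(design(m, n=50_000), seed=31)
            assert 1.0 - data.status.mean() == pytest.approx(0.40, abs=0.012)

    def test_bisection_recovers_cached_value(self):
        c = calibrate_censoring(design("M1"), target=0.40, tol=0.002,
                                seed=6, n=40_000)
        assert c == pytest.approx(CALIBRATED_CENSORING_MEANS["M1"], rel=0.05)

    def test_monotone_in_mean(self):
        from markqr.simulate import _draw_failures

        rng = np.random.default_rng(41)
        _, _, _, T = _draw_failures(design("M1"), 50_000, rng)
        r_small = np.mean(-np.expm1(-T / 1.0))
        r_big = np.mean(-np.expm1(-T / 8.0))
        assert r_small > r_big  # longer censoring times → fewer censorings

    def test_infeasible_target_rejected(self):
        with pytest.raises(MarkQRError):
            calibrate_censoring(design("M1"), target=1e-9, tol=1e-10,
                                seed=0, n=2_000, c_cap=1e3)


class TestToyModel:
    def test_marginal_efficacy_vanishes_in_null_configuration(self):
        oracle = ToyOracle(gamma0=0.25, gamma1=-1.5)  # γ1 = −(2γ0+1)
        taus = np.linspace(0.01, 0.99, 25)
        np.testing.assert_allclose(
            [oracle.marginal_qve(t) for t in taus], 0.0, atol=1e-15
        )

    def test_mark_specific_efficacy_does_not_vanish(self):
        oracle = ToyOracle(gamma0=0.25, gamma1=-1.5)
        assert abs(oracle.qve(0.3, 0.2)) > 0.05
        assert abs(oracle.qve(0.8, 0.2)) > 0.05

    def test_zero_gamma1_kills_efficacy(self):
        oracle = ToyOracle(gamma0=0.25, gamma1=0.0)
        assert oracle.qve(0.3, 0.2) == 0.0
        assert oracle.marginal_qve(0.3) == 0.0

    def test_marginal_quantile_against_numerical_inversion(self):
        """The printed marginal quantile solves F(t|Z1) = τ where
        F(t|Z1) = E_V[min(log t/(V+γ0+γ1Z1)², 1)] — verified by direct
        numerical integration for small τ."""
        from scipy.integrate import quad

        g0, g1 = 0.25, -1.5
        oracle = ToyOracle(g0, g1)
        for z1 in (0.0, 1.0):
            for tau in (0.05, 0.15):
                q = float(oracle.marginal_quantile(tau, z1))

                def cdf(t):
                    val, _ = quad(
                        lambda v: min(np.log(t) / (v + g0 + g1 * z1) ** 2, 1.0),
                        0, 1,
                    )
                    return val

                assert cdf(q) == pytest.approx(tau, abs=1e-7)

    def test_generated_log_times_within_support(self):
        data, oracle = generate_toy(n=5000, seed=3)
        z1 = data.covariates[:, 0]
        width = (data.mark + 0.25 - 1.5 * z1) ** 2
        logs = np.log(data.time)
        assert np.all(logs >= 0.0)
        assert np.all(logs <= width + 1e-12)

    def test_invalid_support_rejected(self):
        with pytest.raises(MarkQRError):
            generate_toy(gamma0=-0.1)
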