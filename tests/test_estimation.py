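"""Localized estimating functions, induced smoothing and the Newton solver."""

import numpy as np
import pytest
from scipy.special import ndtri

from markqr.data import MarkedSurvivalDataset, build_grid
from markqr.estimation import (
    Link,
    estimating_function_raw,
    estimating_function_smoothed,
    fit_field,
    smoothed_jacobian,
    solve_beta,
)


def intercept_only(times, marks, horizon=None):
    times = np.asarray(times, dtype=float)
    data = MarkedSurvivalDataset(
        time=times,
        status=np.ones(times.size),
        mark=np.asarray(marks, dtype=float),
        covariates=np.empty((times.size, 0)),
    )
    h_val = horizon if horizon is not None else float(times.max())
    grid = build_grid(n_mark=6, n_tau=4, h=0.2, horizon=h_val)
    return data, grid


class TestRawEstimatingFunction:
    def test_empty_kernel_window_gives_minus_tau_zbar(self):
        data, grid = intercept_only([1.0, 2.0], [0.05, 0.06])
        out = estimating_function_raw(np.array([0.0]), v=0.5, tau=0.25,
                                      data=data, grid=grid)
        np.testing.assert_allclose(out, [-0.25])

    def test_intercept_saturation_at_large_beta(self):
        data, grid = intercept_only([1.0, 2.0, 3.0], [0.5, 0.52, 0.48])
        w = grid.kernel.scaled(data.mark, 0.5, grid.bandwidth)  # Ĝ ≡ 1
        out = estimating_function_raw(np.array([100.0]), v=0.5, tau=0.3,
                                      data=data, grid=grid)
        np.testing.assert_allclose(out, [w.mean() - 0.3])

    def test_single_observation_step_at_log_t0(self):
        data, grid = intercept_only([2.0], [0.5])
        k0 = grid.kernel.scaled(0.5, 0.5, grid.bandwidth)
        below = estimating_function_raw(np.array([np.log(2.0) - 1e-9]), 0.5, 0.3,
                                        data, grid=grid)
        above = estimating_function_raw(np.array([np.log(2.0) + 1e-9]), 0.5, 0.3,
                                        data, grid=grid)
        np.testing.assert_allclose(below, [-0.3])
        np.testing.assert_allclose(above, [k0 - 0.3])

    def test_monotone_step_function_of_intercept(self):
        rng = np.random.default_rng(3)
        data, grid = intercept_only(rng.lognormal(0, 1, 25), rng.uniform(0, 1, 25))
        betas = np.linspace(-4, 4, 161)
        vals = [
            estimating_function_raw(np.array([b]), 0.5, 0.2, data, grid=grid)[0]
            for b in betas
        ]
        assert np.all(np.diff(vals) >= -1e-12)


class TestInducedSmoothing:
    def test_converges_to_raw_as_scale_shrinks(self):
        rng = np.random.default_rng(5)
        data, grid = intercept_only(rng.lognormal(0, 1, 40), rng.uniform(0, 1, 40))
        # β probe points kept away from the jump locations log X_i
        betas = np.linspace(-3, 3, 97)
        jumps = np.log(data.time)
        far = np.abs(betas[:, None] - jumps[None, :]).min(axis=1) > 0.05
        betas = betas[far]
        sups = []
        for mult in (1.0, 0.3, 0.03):
            diffs = [
                abs(
                    estimating_function_smoothed(
                        np.array([b]), 0.5, 0.2, data, grid=grid,
                        scale_multiplier=mult,
                    )[0]
                    - estimating_function_raw(np.array([b]), 0.5, 0.2, data, grid=grid)[0]
                )
                for b in betas
            ]
            sups.append(max(diffs))
        assert sups[0] > sups[1] > sups[2]
        assert sups[2] < 1e-3

    def test_single_observation_closed_form_root(self):
        # root of k0 Φ((β − log t0)/s) − τ  is  β = log t0 + s Φ⁻¹(τ/k0)
        t0, tau = 2.0, 0.3
        data, grid = intercept_only([t0], [0.5])
        k0 = float(grid.kernel.scaled(0.5, 0.5, grid.bandwidth))
        s = 1.0 / np.sqrt(1 * grid.bandwidth)  # γ = ‖Z‖ = 1, n = 1
        expected = np.log(t0) + s * ndtri(tau / k0)
        beta, diag = solve_beta(0.5, tau, data, grid=grid)
        assert diag["converged"]
        assert beta[0] == pytest.approx(expected, abs=1e-6)
        resid = estimating_function_smoothed(beta, 0.5, tau, data, grid=grid)
        assert abs(resid[0]) <= 1e-8

    def test_root_matches_raw_generalized_root_on_small_samples(self):
        # midpoint of the raw zero-crossing interval, by exhaustive scan
        rng = np.random.default_rng(9)
        for trial in range(5):
            n = int(rng.integers(5, 20))
            data, grid = intercept_only(
                rng.lognormal(0, 1, n), rng.uniform(0.2, 0.8, n)
            )
            tau = 0.25
            beta, diag = solve_beta(0.5, tau, data, grid=grid)
            assert diag["converged"]
            jumps = np.sort(np.log(data.time))
            vals = [
                estimating_function_raw(np.array([b]), 0.5, tau, data, grid=grid)[0]
                for b in np.concatenate([jumps - 1e-9, jumps + 1e-9, [-50, 50]])
            ]
            bgrid = np.concatenate([jumps - 1e-9, jumps + 1e-9, [-50, 50]])
            order = np.argsort(bgrid)
            bgrid, vals = bgrid[order], np.asarray(vals)[order]
            crossing = np.flatnonzero(np.diff(np.sign(vals)) > 0)
            assert crossing.size
            mid = 0.5 * (bgrid[crossing[0]] + bgrid[crossing[0] + 1])
            s_max = 1.0 / np.sqrt(n * grid.bandwidth)
            assert abs(beta[0] - mid) <= 2 * s_max

    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        data, grid = intercept_only(rng.lognormal(0, 1, 30), rng.uniform(0, 1, 30))
        beta = np.array([0.3])
        J = smoothed_jacobian(beta, 0.5, 0.2, data, grid=grid)
        eps = 1e-6
        fd = (
            estimating_function_smoothed(beta + eps, 0.5, 0.2, data, grid=grid)
            - estimating_function_smoothed(beta - eps, 0.5, 0.2, data, grid=grid)
        ) / (2 * eps)
        assert J[0, 0] == pytest.approx(fd[0], rel=1e-5)


class TestSolveAndField:
    def test_time_rescaling_shifts_only_intercept(self, m2_data, m2_grid):
        c = 7.3
        scaled = MarkedSurvivalDataset(
            time=m2_data.time * c,
            status=m2_data.status,
            mark=m2_data.mark,
            covariates=m2_data.covariates,
        )
        f1 = fit_field(m2_data, None, m2_grid)
        f2 = fit_field(scaled, None, m2_grid.with_horizon(m2_grid.horizon * c))
        assert f1.converged.all() and f2.converged.all()
        shift = f2.beta[:, :, 0] - f1.beta[:, :, 0]
        np.testing.assert_allclose(shift, np.log(c), atol=1e-6)
        np.testing.assert_allclose(f2.beta[:, :, 1:], f1.beta[:, :, 1:], atol=1e-6)

    def test_full_grid_converges_with_warm_starts(self, m2_field):
        assert m2_field.n_unconverged == 0
        assert np.all(m2_field.residual_norm <= 1e-8)
        assert np.all(np.isfinite(m2_field.beta))

    def test_explicit_exp_link_reproduces_default(self, m2_data, m2_grid):
        f_default = fit_field(m2_data, None, m2_grid)
        hook = Link(name="exp", forward=np.exp, inverse=np.log)
        f_hook = fit_field(m2_data, None, m2_grid, link=hook)
        np.testing.assert_array_equal(f_default.beta, f_hook.beta)

    def test_iterative_gamma_policy_agrees_with_identity(self):
        from markqr.simulate import design, generate
        from markqr.variance import pointwise_covariance

        data = generate(design("M1", n=400), seed=27)
        grid = build_grid(n_mark=3, n_tau=3, h=0.25, horizon=data)
        f_id = fit_field(data, None, grid, gamma_policy="identity")
        f_it = fit_field(data, None, grid, gamma_policy="iterative")
        cov = pointwise_covariance(f_id)
        se = np.sqrt(np.einsum("vtii->vti", cov.Omega) / (data.n * grid.bandwidth))
        assert np.all(np.abs(f_it.beta - f_id.beta) <= se)

    def test_degenerate_window_flagged_not_raised(self):
        # marks concentrated near 0.1: windows near v = 0.8 are empty
        rng = np.random.default_rng(13)
        n = 40
        data = MarkedSurvivalDataset(
            time=rng.lognormal(0, 1, n),
            status=np.ones(n),
            mark=rng.uniform(0.0, 0.2, n),
            covariates=np.empty((n, 0)),
        )
        grid = build_grid(a=0.1, b=0.9, n_mark=5, n_tau=3, h=0.1,
                          horizon=float(data.time.max()))
        with pytest.warns(UserWarning):
            field = fit_field(data, None, grid)
        assert field.n_unconverged > 0
        assert np.isnan(field.beta[-1]).all()
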