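"""Cumulative coefficients, ω̂, influence functions φ̂1/φ̂2, and Ψ̂."""

import numpy as np
import pytest

from markqr.cumulative import (
    InfluenceSet,
    _cumtrapz,
    cumulative_beta,
    influence_set,
    omega_fn,
    psi_hat,
)
from markqr.data import MarkQRError, MarkedSurvivalDataset, build_grid
from markqr.estimation import fit_field
from markqr.simulate import design, generate


@pytest.fixture(scope="module")
def m2_influence(m2_field, m2_cov):
    return influence_set(m2_field, m2_cov)


class TestCumulativeBeta:
    def test_zero_at_lower_mark_endpoint(self, m2_field):
        B = cumulative_beta(m2_field)
        np.testing.assert_array_equal(B[0], 0.0)

    def test_constant_integrand_gives_linear_growth(self):
        x = np.linspace(0.3, 0.8, 11)
        y = np.full((11, 1, 2), 3.0)
        out = _cumtrapz(y, x, axis=0)
        np.testing.assert_allclose(out[:, 0, 0], 3.0 * (x - 0.3), atol=1e-12)

    def test_unconverged_cells_raise_with_location(self, m2_field):
        import copy

        broken = copy.copy(m2_field)
        broken.converged = m2_field.converged.copy()
        broken.converged[3, 2] = False
        with pytest.raises(MarkQRError, match=r"\[3, 2\]"):
            cumulative_beta(broken)

    def test_trapezoid_close_to_midpoint_rule_on_grid(self, m2_field):
        # resolution check: two quadrature rules agree to ~1% on cqve-type
        # integrals of a fitted, smoothly varying coefficient path
        g = m2_field.grid
        y = m2_field.beta[:, 2, 2]
        x = g.mark_points
        trap = np.trapezoid(y, x)
        mid = np.sum(0.5 * (y[1:] + y[:-1]) * np.diff(x))  # same nodes
        assert trap == pytest.approx(mid, rel=1e-12)


class TestOmegaFn:
    def test_zero_beyond_last_event_time(self, m2_field):
        s_big = float(m2_field.data.time.max()) + 1.0
        out = omega_fn(s_big, 0.5, m2_field, tau_index=2)
        np.testing.assert_array_equal(out, 0.0)

    def test_brute_force_double_loop_matches(self, m2_field):
        ws = m2_field.workspace
        grid = m2_field.grid
        iu, it = 6, 4
        u = grid.mark_points[iu]
        beta = m2_field.beta[iu, it]
        for s in (0.0, 0.8, 2.0):
            expected = np.zeros(ws.q)
            for i in range(ws.n):
                if ws.event_ok[i] and abs(ws.V[i] - u) < grid.bandwidth:
                    upper = np.exp(ws.Z[i] @ beta)
                    if s <= ws.X[i] <= upper:
                        kh = grid.kernel.scaled(ws.V[i], u, grid.bandwidth)
                        expected += ws.Z[i] * kh * ws.inv_G[i]
            expected /= ws.n
            np.testing.assert_allclose(
                omega_fn(s, u, m2_field, it), expected, atol=1e-12
            )

    def test_monotone_nonincreasing_in_s(self, m2_field):
        s_grid = np.linspace(0.0, 3.0, 7)
        vals = np.array([omega_fn(s, 0.55, m2_field, 3)[0] for s in s_grid])
        assert np.all(np.diff(vals) <= 1e-12)


class TestInfluences:
    def test_phi_vanish_at_lower_endpoint(self, m2_influence):
        np.testing.assert_array_equal(m2_influence.phi1_matrix(0, 2), 0.0)
        np.testing.assert_array_equal(m2_influence.phi2_matrix(0, 2), 0.0)

    def test_censored_subject_phi1_is_pure_drift(self, m2_influence, m2_data):
        """For Δ_i = 0 the event atom is absent: φ̂1i = −τ[∫Â⁻¹du]Z_i."""
        grid = m2_influence.field.grid
        iv, it = grid.n_mark - 1, 3
        tau = grid.tau_points[it]
        marks = grid.mark_points[: iv + 1]
        Ainv_path = np.array([
            m2_influence.cov.A_inv[k, it] for k in range(iv + 1)
        ])
        drift = np.trapezoid(Ainv_path, marks, axis=0)
        phi1 = m2_influence.phi1_matrix(iv, it)
        cens = np.flatnonzero(m2_data.status == 0.0)[:5]
        for i in cens:
            np.testing.assert_allclose(
                phi1[i], -tau * drift @ m2_data.design[i], atol=1e-10
            )

    def test_mean_phi1_bounded_by_jump_size(self, m2_influence, m2_data):
        """n⁻¹Σφ̂1i integrates U_n(β̂) against Â⁻¹; at the smoothed root
        U_n is only within the largest single-subject jump of zero."""
        grid = m2_influence.field.grid
        iv, it = grid.n_mark - 1, 5
        mean_phi = m2_influence.phi1_matrix(iv, it).mean(axis=0)
        ws = m2_influence.field.workspace
        jump = 0.0
        norm_Ainv = 0.0
        for k in range(iv + 1):
            idx, Za, ya, wa = ws.cell_arrays(grid.mark_points[k])
            if idx.size:
                jump = max(jump, float((wa[:, None] * np.abs(Za)).max()) / ws.n)
            norm_Ainv = max(
                norm_Ainv, float(np.abs(m2_influence.cov.A_inv[k, it]).max())
            )
        v_len = grid.mark_points[iv] - grid.mark_points[0]
        bound = 3.0 * ws.q * norm_Ainv * jump * v_len
        assert np.abs(mean_phi).max() <= bound

    def test_phi2_zero_without_censoring(self):
        rng = np.random.default_rng(21)
        n = 120
        data = MarkedSurvivalDataset(
            time=rng.lognormal(0, 0.5, n),
            status=np.ones(n),
            mark=rng.uniform(0, 1, n),
            covariates=rng.uniform(0, 1, (n, 1)),
        )
        grid = build_grid(n_mark=5, n_tau=3, h=0.3, horizon=float(data.time.max()))
        field = fit_field(data, None, grid)
        infl = influence_set(field)
        np.testing.assert_array_equal(infl.phi2_matrix(4, 2), 0.0)


class TestPsi:
    def test_zero_at_lower_endpoint_pair(self, m2_influence):
        g = m2_influence.field.grid
        a, t0 = g.mark_points[0], g.tau_points[0]
        np.testing.assert_array_equal(psi_hat(m2_influence, a, a, t0, t0), 0.0)

    def test_diagonal_blocks_symmetric_psd(self, m2_influence):
        g = m2_influence.field.grid
        rng = np.random.default_rng(2)
        for _ in range(6):
            v = g.mark_points[rng.integers(1, g.n_mark)]
            t = g.tau_points[rng.integers(g.n_tau)]
            P = psi_hat(m2_influence, v, v, t, t)
            np.testing.assert_allclose(P, P.T, atol=1e-10)
            assert np.linalg.eigvalsh(P).min() >= -1e-10

    def test_transpose_identity_across_cells(self, m2_influence):
        g = m2_influence.field.grid
        v1, v2 = g.mark_points[4], g.mark_points[9]
        t1, t2 = g.tau_points[1], g.tau_points[6]
        P12 = psi_hat(m2_influence, v1, v2, t1, t2)
        P21 = psi_hat(m2_influence, v2, v1, t2, t1)
        np.testing.assert_allclose(P12, P21.T, atol=1e-12)

    def test_off_grid_arguments_rejected(self, m2_influence):
        with pytest.raises(MarkQRError, match="grid node"):
            psi_hat(m2_influence, 0.512341, 0.6, 0.2, 0.2)

    def test_tracks_replication_variance_of_cumulative_coefficient(self):
        """n·Var(B̂1) from Ψ̂ against the empirical replication variance
        (small design, generous band: stochastic cross-check)."""
        des = design("M2", n=500)
        grid_kw = dict(n_mark=8, n_tau=1, tau0=0.2, tauU=0.2, h=0.25)
        psi_vals, B_vals = [], []
        for r in range(60):
            data = generate(des, seed=900 + r)
            grid = build_grid(horizon=data, **grid_kw)
            field = fit_field(data, None, grid)
            infl = influence_set(field)
            B = cumulative_beta(field)
            B_vals.append(B[-1, 0, 1])
            P = psi_hat(infl, grid.b, grid.b, 0.2, 0.2)
            psi_vals.append(P[1, 1] / data.n)
        emp = np.var(B_vals, ddof=1)
        est = np.mean(psi_vals)
        assert est == pytest.approx(emp, rel=0.5)
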