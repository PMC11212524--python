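"""Pointwise sandwich covariance of β̂_τ(v).

Asymptotically, (nh)^{1/2}{β̂_τ(v) − β*_τ(v)} is
normal with covariance Ω_τ(v) = A_τ(v)⁻¹ D(v,τ) A_τ(v)⁻¹.  The plug-in
estimators are

    Â_τ(v) = n^{-1/2} h^{1/2} Σ_i Δ_i Z_iZ_i' Ĝ(X_i-)⁻¹ γ_i⁻¹
             φ{(Z_i'β̂ − log X_i)/((nh)^{-1/2}γ_i)} K_h(V_i − v),
    D̂(v,τ) = n⁻¹ h Σ_i η̂_i η̂_i',
    η̂_i    = Z_i[Δ_i I(X_i ≤ L) I{log X_i ≤ Z_i'β̂} K_h(V_i − v)
                 Ĝ(X_i-)⁻¹ − τ],

and the standard error of β̂_j is (Ω̂_jj/(nh))^{1/2}.  Â coincides exactly
with the analytic Jacobian of the smoothed system at β̂ (same weights,
same normal density), which is pinned by a unit test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MarkQRError
from .estimation import _SQRT2PI, CoefficientField

__all__ = [
    "PointwiseCovariance",
    "A_hat",
    "D_hat",
    "omega_hat",
    "pointwise_covariance",
]

_COND_MAX = 1e12


def _cell_eta_weights(field: CoefficientField, iv: int, it: int, beta=None):
    """Per-subject scalar g_i = w_i I{log X_i ≤ Z_i'β̂} − τ over all n."""
    ws = field.workspace
    v = field.grid.mark_points[iv]
    tau = field.grid.tau_points[it]
    if beta is None:
        beta = field.beta[iv, it]
    idx, Za, ya, wa = ws.cell_arrays(v)
    g = np.full(ws.n, -tau)
    if idx.size:
        g[idx] += wa * (ya <= Za @ beta)
    return g


def A_hat_cell(
    field: CoefficientField,
    iv: int,
    it: int,
    beta_override: np.ndarray | None = None,
    Gamma: np.ndarray | None = None,
) -> np.ndarray:
    """Â_τ(v) at one grid cell (symmetric PSD; zero if the window is empty)."""
    ws = field.workspace
    v = field.grid.mark_points[iv]
    beta = field.beta[iv, it] if beta_override is None else beta_override
    idx, Za, ya, wa = ws.cell_arrays(v)
    q = ws.q
    if idx.size == 0 or np.any(np.isnan(beta)):
        return np.zeros((q, q))
    gam = ws.gamma(Gamma)[idx]
    e = (Za @ beta - ya) * ws.root_nh / gam
    dens = np.exp(-0.5 * e * e) / _SQRT2PI
    scale = np.sqrt(field.grid.bandwidth / ws.n)
    return scale * np.einsum("i,ij,ik->jk", wa * dens / gam, Za, Za)


def D_hat_cell(
    field: CoefficientField,
    iv: int,
    it: int,
    beta_override: np.ndarray | None = None,
) -> np.ndarray:
    """D̂(v,τ) = n⁻¹ h Σ η̂_i η̂_i' at one grid cell."""
    ws = field.workspace
    g = _cell_eta_weights(field, iv, it, beta=beta_override)
    return (field.grid.bandwidth / ws.n) * np.einsum("i,ij,ik->jk", g * g, ws.Z, ws.Z)


def A_hat(field: CoefficientField, iv: int, it: int) -> np.ndarray:
    """Public per-cell Â accessor."""
    return A_hat_cell(field, iv, it)


def D_hat(field: CoefficientField, iv: int, it: int) -> np.ndarray:
    """Public per-cell D̂ accessor."""
    return D_hat_cell(field, iv, it)


def omega_hat(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Sandwich Ω̂ = Â⁻¹ D̂ Â⁻¹ with a condition-number guard."""
    if not np.all(np.isfinite(A)) or np.linalg.cond(A) > _COND_MAX:
        raise MarkQRError("Â is singular or ill-conditioned; Ω̂ undefined at this cell")
    Ai = np.linalg.inv(A)
    Om = Ai @ D @ Ai
    return 0.5 * (Om + Om.T)


@dataclass
class PointwiseCovariance:
    """Â, D̂ and Ω̂ on the whole grid, with per-cell validity flags.

    Shapes are (n_mark, n_tau, p+1, p+1); ``ok`` marks cells where the
    solver converged and Â was invertible.  ``se(j)`` returns the standard
    error surface of coefficient j: (Ω̂_jj/(nh))^{1/2}.
    """

    A: np.ndarray
    D: np.ndarray
    Omega: np.ndarray
    A_inv: np.ndarray
    ok: np.ndarray
    field: CoefficientField

    def se(self, coef: int) -> np.ndarray:
        nh = self.field.workspace.nh
        return np.sqrt(np.clip(self.Omega[:, :, coef, coef], 0.0, None) / nh)

    def to_frame(self):
        import pandas as pd

        grid = self.field.grid
        nv, nt, q, _ = self.Omega.shape
        vv, tt, ii, jj = np.meshgrid(
            grid.mark_points, grid.tau_points, np.arange(q), np.arange(q), indexing="ij"
        )
        return pd.DataFrame({
            "v": vv.ravel(), "tau": tt.ravel(),
            "i": ii.ravel(), "j": jj.ravel(),
            "omega": self.Omega.ravel(),
        })


def pointwise_covariance(field: CoefficientField) -> PointwiseCovariance:
    """Compute Â, D̂, Ω̂ at every converged grid cell (vectorized over τ)."""
    ws = field.workspace
    grid = field.grid
    nv, nt, q = grid.n_mark, grid.n_tau, ws.q
    A = np.zeros((nv, nt, q, q))
    D = np.zeros((nv, nt, q, q))
    Omega = np.full((nv, nt, q, q), np.nan)
    A_inv = np.full((nv, nt, q, q), np.nan)
    ok = np.zeros((nv, nt), bool)
    taus = grid.tau_points
    # covariate part of D that does not depend on the window: τ² ZZ̄'
    ZZ = np.einsum("ij,ik->jk", ws.Z, ws.Z)
    scale_A = np.sqrt(grid.bandwidth / ws.n)
    scale_D = grid.bandwidth / ws.n
    for iv, v in enumerate(grid.mark_points):
        idx, Za, ya, wa = ws.cell_arrays(v)
        if idx.size == 0:
            continue
        gam = ws.gamma(None)[idx]
        B = field.beta[iv]  # (nt, q)
        good = field.converged[iv] & ~np.isnan(B[:, 0])
        if not good.any():
            continue
        e = (B[good] @ Za.T - ya[None, :]) * (ws.root_nh / gam)[None, :]
        dens = np.exp(-0.5 * e * e) / _SQRT2PI
        A[iv, good] = scale_A * np.einsum(
            "tm,mj,mk->tjk", dens * (wa / gam)[None, :], Za, Za
        )
        ind = (ya[None, :] <= B[good] @ Za.T).astype(float)
        wind = wa[None, :] * ind  # (T_good, m)
        # D = h/n [ Σ_all τ²ZZ' + Σ_win ((w·ind − τ)² − τ²) ZZ' ]
        tau_g = taus[good]
        base = tau_g[:, None, None] ** 2 * ZZ[None]
        corr = np.einsum("tm,mj,mk->tjk", wind * wind - 2.0 * tau_g[:, None] * wind, Za, Za)
        D[iv, good] = scale_D * (base + corr)
        rows = np.flatnonzero(good)
        conds = np.linalg.cond(A[iv, rows])
        inv_ok = np.isfinite(conds) & (conds < _COND_MAX)
        rows = rows[inv_ok]
        if rows.size:
            Ai = np.linalg.inv(A[iv, rows])
            A_inv[iv, rows] = Ai
            Om = Ai @ D[iv, rows] @ Ai
            Omega[iv, rows] = 0.5 * (Om + np.swapaxes(Om, -1, -2))
            ok[iv, rows] = True
    return PointwiseCovariance(A=A, D=D, Omega=Omega, A_inv=A_inv, ok=ok, field=field)
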