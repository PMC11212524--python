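"""Induced-smoothing estimation of the mark-specific quantile model.

The model is Q_v(τ|Z) = H{Z'β*_τ(v)} with log link H = exp by default: the
τ-th mark-specific quantile of the failure time, localized at mark v, is
log-linear in the design vector Z = (1, Z̃')'.  β*_τ(v) solves the
kernel-localized, IPCW-weighted estimating equation U_n(β) = 0 with

    U_n(β) = n⁻¹ Σ_i Z_i [ Δ_i Ĝ(X_i-)⁻¹ I(X_i ≤ L) I{log X_i ≤ Z_i'β}
                           K_h(V_i − v) − τ ],

a monotone but discontinuous step function of β.  Induced smoothing
replaces the indicator with Φ{(Z_i'β − log X_i)/s_i}, the expectation of
the indicator under a small Gaussian perturbation β + (nh)^{-1/2} Γ W of
the parameter, where s_i = (nh)^{-1/2} γ_i and γ_i = (Z_i'ΓΓ'Z_i)^{1/2}.
The smoothed system Ŝ_n is continuously differentiable with a symmetric
positive semidefinite Jacobian, so damped Newton iterations converge.

``fit_field`` solves cell-by-cell over a mark × quantile grid with warm
starts, vectorizing the Newton iterations across quantile levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import ndtr

from .censoring import CensoringModel, check_positivity, fit_censoring
from .data import EvaluationGrid, MarkedSurvivalDataset, MarkQRError, default_horizon

__all__ = [
    "Link",
    "LOG_LINK",
    "CoefficientField",
    "estimating_function_raw",
    "estimating_function_smoothed",
    "smoothed_jacobian",
    "solve_beta",
    "fit_field",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class Link:
    """Monotone positive link H with Q_v(τ|Z) = H(Z'β).

    Only ``inverse`` enters the estimating equation (through the residuals
    H⁻¹(X_i) − Z_i'β); ``forward`` is needed for fitted quantiles and the
    time thresholds of the influence machinery.
    """

    name: str
    forward: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]


LOG_LINK = Link(name="exp", forward=np.exp, inverse=np.log)


def _resolve_link(link) -> Link:
    if link is None or link == "exp" or link == "log":
        return LOG_LINK
    if isinstance(link, Link):
        return link
    raise MarkQRError(f"unrecognized link {link!r}")


# ---------------------------------------------------------------------------
# per-fit workspace
# ---------------------------------------------------------------------------

class _Workspace:
    """Precomputed arrays shared by every grid cell of one fit."""

    def __init__(
        self,
        data: MarkedSurvivalDataset,
        censoring: CensoringModel,
        grid: EvaluationGrid,
        link: Link = LOG_LINK,
        gamma_sqrt: bool = True,
    ):
        self.data = data
        self.censoring = censoring
        self.grid = grid
        self.link = link
        self.gamma_sqrt = gamma_sqrt
        L = grid.horizon
        if not np.isfinite(L):
            L = default_horizon(data)
            self.grid = grid = grid.with_horizon(L)
        check_positivity(censoring, L)
        self.n = data.n
        self.q = data.p + 1
        self.Z = data.design
        self.Zbar = self.Z.mean(axis=0)
        self.X = data.time
        self.y = link.inverse(data.time)
        self.delta = data.status
        self.event_ok = (data.status == 1.0) & (data.time <= L)
        Gm = censoring.G_minus(data.time)
        if np.any(Gm[self.event_ok] <= 0.0):
            raise MarkQRError("Ĝ(X-) = 0 at an event before L; positivity violated")
        self.inv_G = np.zeros(self.n)
        self.inv_G[self.event_ok] = 1.0 / Gm[self.event_ok]
        self.V = data.mark
        # events sorted by mark for O(log n) window lookup
        ev = np.flatnonzero(self.event_ok)
        order = np.argsort(self.V[ev], kind="stable")
        self.ev_sorted = ev[order]
        self.ev_marks = self.V[self.ev_sorted]
        self.nh = self.n * grid.bandwidth
        self.root_nh = np.sqrt(self.nh)
        self._gamma_identity = self._gamma_from(np.eye(self.q))

    def _gamma_from(self, Gamma: np.ndarray) -> np.ndarray:
        quad = np.einsum("ij,jk,ik->i", self.Z, Gamma @ Gamma.T, self.Z)
        return np.sqrt(quad) if self.gamma_sqrt else quad

    def gamma(self, Gamma: np.ndarray | None) -> np.ndarray:
        if Gamma is None:
            return self._gamma_identity
        return self._gamma_from(np.asarray(Gamma, dtype=float))

    def window(self, v: float) -> np.ndarray:
        """Indices of usable events with |V_i - v| < h."""
        h = self.grid.bandwidth
        lo = np.searchsorted(self.ev_marks, v - h, side="right")
        hi = np.searchsorted(self.ev_marks, v + h, side="left")
        return self.ev_sorted[lo:hi]

    def cell_arrays(self, v: float):
        """(indices, Z_act, y_act, w_act) for the kernel window at v."""
        idx = self.window(v)
        w = self.grid.kernel.scaled(self.V[idx], v, self.grid.bandwidth) * self.inv_G[idx]
        return idx, self.Z[idx], self.y[idx], w


def _workspace(data, censoring, grid, link=None, gamma_sqrt=True) -> _Workspace:
    if censoring is None:
        censoring = fit_censoring(data)
    return _Workspace(data, censoring, grid, _resolve_link(link), gamma_sqrt)


# ---------------------------------------------------------------------------
# estimating functions (single cell, reference implementations)
# ---------------------------------------------------------------------------

def estimating_function_raw(
    beta: np.ndarray,
    v: float,
    tau: float,
    data: MarkedSurvivalDataset,
    censoring: CensoringModel | None = None,
    grid: EvaluationGrid | None = None,
    link=None,
) -> np.ndarray:
    """Non-smooth localized estimating function U_n(β) at one (v, τ)."""
    ws = _workspace(data, censoring, grid, link)
    idx, Za, ya, wa = ws.cell_arrays(v)
    ind = (ya <= Za @ np.asarray(beta, dtype=float)).astype(float)
    return (Za * (wa * ind)[:, None]).sum(axis=0) / ws.n - tau * ws.Zbar


def estimating_function_smoothed(
    beta: np.ndarray,
    v: float,
    tau: float,
    data: MarkedSurvivalDataset,
    censoring: CensoringModel | None = None,
    grid: EvaluationGrid | None = None,
    Gamma: np.ndarray | None = None,
    link=None,
    scale_multiplier: float = 1.0,
    gamma_sqrt: bool = True,
) -> np.ndarray:
    """Induced-smoothed estimating function Ŝ_n(β) at one (v, τ).

    ``scale_multiplier`` rescales the per-subject smoothing scale s_i
    (useful for annealing and for checking Ŝ_n → U_n as the scale shrinks).
    """
    ws = _workspace(data, censoring, grid, link, gamma_sqrt)
    idx, Za, ya, wa = ws.cell_arrays(v)
    s = scale_multiplier * ws.gamma(Gamma)[idx] / ws.root_nh
    e = (Za @ np.asarray(beta, dtype=float) - ya) / s
    return (Za * (wa * ndtr(e))[:, None]).sum(axis=0) / ws.n - tau * ws.Zbar


def smoothed_jacobian(
    beta: np.ndarray,
    v: float,
    tau: float,
    data: MarkedSurvivalDataset,
    censoring: CensoringModel | None = None,
    grid: EvaluationGrid | None = None,
    Gamma: np.ndarray | None = None,
    link=None,
    gamma_sqrt: bool = True,
) -> np.ndarray:
    """Analytic Jacobian ∂Ŝ_n/∂β: symmetric positive semidefinite."""
    ws = _workspace(data, censoring, grid, link, gamma_sqrt)
    idx, Za, ya, wa = ws.cell_arrays(v)
    s = ws.gamma(Gamma)[idx] / ws.root_nh
    e = (Za @ np.asarray(beta, dtype=float) - ya) / s
    dens = np.exp(-0.5 * e * e) / _SQRT2PI
    return np.einsum("i,ij,ik->jk", wa * dens / s, Za, Za) / ws.n


# ---------------------------------------------------------------------------
# batched Newton solver
# ---------------------------------------------------------------------------

def _batched_solve(
    ws: _Workspace,
    v: float,
    taus: np.ndarray,
    init: np.ndarray,
    gamma_vec: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    max_halvings: int = 30,
    scale_multiplier: float = 1.0,
    ridge: float = 1e-10,
):
    """Damped Newton for all quantile levels at a fixed mark point.

    Returns (beta: (T, q), converged: (T,), residual: (T,)).  Cells whose
    kernel window contains no usable event are flagged unconverged with
    NaN coefficients (the estimating function has no root there).
    """
    taus = np.asarray(taus, dtype=float)
    T, q = taus.size, ws.q
    idx, Za, ya, wa = ws.cell_arrays(v)
    if idx.size == 0:
        return np.full((T, q), np.nan), np.zeros(T, bool), np.full(T, np.inf)
    s = scale_multiplier * gamma_vec[idx] / ws.root_nh
    inv_s = 1.0 / s
    tZ = taus[:, None] * ws.Zbar[None, :]
    eye = np.eye(q)

    def S_of(B, tz=tZ):
        e = (B @ Za.T - ya[None, :]) * inv_s[None, :]
        return ndtr(e) * wa[None, :] @ Za / ws.n - tz, e

    B = np.array(init, dtype=float, copy=True)
    S, e = S_of(B)
    res = np.abs(S).max(axis=1)
    stalled = np.zeros(T, bool)
    for _ in range(max_iter):
        active = (res > tol) & ~stalled
        if not active.any():
            break
        dens = np.exp(-0.5 * e * e) / _SQRT2PI
        wgt = (dens * (wa * inv_s)[None, :]) / ws.n  # (T, m)
        J = np.einsum("tm,mj,mk->tjk", wgt[active], Za, Za) + ridge * eye
        step = np.linalg.solve(J, -S[active][..., None])[..., 0]
        # damping: accept the first step fraction that strictly lowers the
        # residual sup-norm; a cell with no acceptable fraction stalls
        # (plateau of the saturated equation) and keeps its iterate
        tZ_act = tZ[active]
        B_act = B[active]
        res_act = res[active]
        best_B = B_act.copy()
        improved = np.zeros(B_act.shape[0], bool)
        lam = 1.0
        for _ in range(max_halvings + 1):
            need = ~improved
            if not need.any():
                break
            trial = B_act[need] + lam * step[need]
            S_try, _ = S_of(trial, tZ_act[need])
            r_try = np.abs(S_try).max(axis=1)
            take = r_try < res_act[need]
            rows = np.flatnonzero(need)[take]
            best_B[rows] = trial[take]
            improved[rows] = True
            lam *= 0.5
        act_rows = np.flatnonzero(active)
        stalled[act_rows[~improved]] = True
        B[act_rows[improved]] = best_B[improved]
        S, e = S_of(B)
        res = np.abs(S).max(axis=1)
    return B, res <= tol, res


def solve_beta(
    v: float,
    tau: float,
    data: MarkedSurvivalDataset,
    censoring: CensoringModel | None = None,
    grid: EvaluationGrid | None = None,
    init: np.ndarray | None = None,
    Gamma: np.ndarray | None = None,
    link=None,
    tol: float = 1e-8,
    max_iter: int = 100,
    gamma_sqrt: bool = True,
):
    """Solve Ŝ_n(β) = 0 at one (v, τ).

    Returns (β̂, diagnostics dict).  Without an initial value the solve is
    annealed: the smoothing scale is inflated by 10 and 3 before the final
    pass, which convexifies the early iterations.
    """
    ws = _workspace(data, censoring, grid, link, gamma_sqrt)
    gamma_vec = ws.gamma(Gamma)
    taus = np.array([tau])
    if init is None:
        idx, Za, ya, wa = ws.cell_arrays(v)
        B = np.zeros((1, ws.q))
        if idx.size:
            B[0, 0] = np.median(ya)
        for mult in (10.0, 3.0, 1.0):
            B, conv, res = _batched_solve(
                ws, v, taus, B, gamma_vec, tol=tol, max_iter=max_iter,
                scale_multiplier=mult,
            )
            if np.any(np.isnan(B)):
                break
    else:
        B, conv, res = _batched_solve(
            ws, v, taus, np.atleast_2d(np.asarray(init, dtype=float)),
            gamma_vec, tol=tol, max_iter=max_iter,
        )
    return B[0], {"converged": bool(conv[0]), "residual_norm": float(res[0])}


# ---------------------------------------------------------------------------
# whole-grid fit
# ---------------------------------------------------------------------------

@dataclass
class CoefficientField:
    """β̂_τ(v) over an evaluation grid, with solver diagnostics.

    ``beta`` has shape (n_mark, n_tau, p + 1); ``converged`` and
    ``residual_norm`` are (n_mark, n_tau).  The workspace handle lets the
    variance/influence modules reuse precomputed arrays.
    """

    beta: np.ndarray
    converged: np.ndarray
    residual_norm: np.ndarray
    grid: EvaluationGrid
    link: Link
    gamma_policy: str
    data: MarkedSurvivalDataset = field(repr=False)
    censoring: CensoringModel = field(repr=False)
    workspace: _Workspace = field(repr=False)

    @property
    def n_unconverged(self) -> int:
        return int((~self.converged).sum())

    def cell(self, iv: int, it: int) -> np.ndarray:
        return self.beta[iv, it]

    def beta_at_mark(self, v: float, it: int) -> np.ndarray:
        """Linear interpolation of β̂_τ(·) at an off-grid mark value."""
        marks = self.grid.mark_points
        return np.array([
            np.interp(v, marks, self.beta[:, it, j]) for j in range(self.beta.shape[2])
        ])

    def to_frame(self):
        """Tidy long-format view: one row per (v, τ, coefficient)."""
        import pandas as pd

        nv, nt, q = self.beta.shape
        vv, tt, jj = np.meshgrid(
            self.grid.mark_points, self.grid.tau_points, np.arange(q), indexing="ij"
        )
        return pd.DataFrame({
            "v": vv.ravel(),
            "tau": tt.ravel(),
            "coef_index": jj.ravel(),
            "estimate": self.beta.ravel(),
            "converged": np.repeat(self.converged.ravel(), q),
            "residual": np.repeat(self.residual_norm.ravel(), q),
        })


def fit_field(
    data: MarkedSurvivalDataset,
    censoring: CensoringModel | None = None,
    grid: EvaluationGrid | None = None,
    link=None,
    gamma_policy: str = "identity",
    tol: float = 1e-8,
    max_iter: int = 100,
    gamma_sqrt: bool = True,
    warn_threshold: float = 0.10,
) -> CoefficientField:
    """Fit β̂_τ(v) over the whole evaluation grid.

    The grid is traversed in increasing v; within a mark point all quantile
    levels are solved jointly by a vectorized damped-Newton iteration.  The
    first column is annealed from a heavily smoothed system; subsequent
    columns warm-start at the neighbouring solution (β*_τ(v) is continuous
    in v).

    ``gamma_policy`` is ``"identity"`` (Γ = I, the default) or
    ``"iterative"`` (alternate between solving with Γ = Ω̂^{1/2} and
    updating Ω̂ until both stabilize — accurate but slow).
    """
    if grid is None:
        grid = _default_grid_for(data)
    if gamma_policy not in ("identity", "iterative"):
        raise MarkQRError("gamma_policy must be 'identity' or 'iterative'")
    ws = _workspace(data, censoring, grid, link, gamma_sqrt)
    grid = ws.grid  # horizon may have been resolved
    gamma_vec = ws.gamma(None)
    nv, nt, q = grid.n_mark, grid.n_tau, ws.q
    beta = np.empty((nv, nt, q))
    conv = np.zeros((nv, nt), bool)
    resid = np.empty((nv, nt))
    taus = grid.tau_points

    prev: np.ndarray | None = None
    for iv, v in enumerate(grid.mark_points):
        if prev is None or np.any(np.isnan(prev)):
            idx, Za, ya, wa = ws.cell_arrays(v)
            B = np.zeros((nt, q))
            if idx.size:
                B[:, 0] = np.median(ya)
            if prev is not None and not np.all(np.isnan(prev)):
                ok = ~np.isnan(prev[:, 0])
                B[ok] = prev[ok]
            for mult in (10.0, 3.0, 1.0):
                B, c, r = _batched_solve(
                    ws, v, taus, B, gamma_vec, tol=tol, max_iter=max_iter,
                    scale_multiplier=mult,
                )
                if np.any(np.isnan(B)):
                    break
        else:
            B, c, r = _batched_solve(
                ws, v, taus, prev, gamma_vec, tol=tol, max_iter=max_iter
            )
        beta[iv], conv[iv], resid[iv] = B, c, r
        prev = B.copy() if not np.any(np.isnan(B)) else None

    fld = CoefficientField(
        beta=beta, converged=conv, residual_norm=resid, grid=grid,
        link=ws.link, gamma_policy=gamma_policy, data=data,
        censoring=ws.censoring, workspace=ws,
    )
    if gamma_policy == "iterative":
        _iterative_gamma_update(fld, tol=1e-4, max_rounds=10)
    frac_bad = fld.n_unconverged / (nv * nt)
    if frac_bad > warn_threshold:
        import warnings

        warnings.warn(
            f"{100 * frac_bad:.1f}% of grid cells failed to converge; "
            "inspect bandwidth/horizon settings",
            stacklevel=2,
        )
    return fld


def _default_grid_for(data: MarkedSurvivalDataset):
    from .data import build_grid

    return build_grid(horizon=data)


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root with negative eigenvalues clipped at 0."""
    sym = 0.5 * (M + M.T)
    w, U = np.linalg.eigh(sym)
    return (U * np.sqrt(np.clip(w, 0.0, None))) @ U.T


def _iterative_gamma_update(field: CoefficientField, tol: float, max_rounds: int) -> None:
    """Refine each cell by alternating Γ = Ω̂^{1/2} and re-solving."""
    from .variance import A_hat_cell, D_hat_cell  # local import avoids a cycle

    ws = field.workspace
    grid = field.grid
    for iv, v in enumerate(grid.mark_points):
        for it, tau in enumerate(grid.tau_points):
            if not field.converged[iv, it]:
                continue
            beta = field.beta[iv, it]
            Gamma = None
            for _ in range(max_rounds):
                A = A_hat_cell(field, iv, it, beta_override=beta, Gamma=Gamma)
                D = D_hat_cell(field, iv, it, beta_override=beta)
                try:
                    Ai = np.linalg.inv(A)
                except np.linalg.LinAlgError:
                    break
                Omega = Ai @ D @ Ai
                Gamma_new = _psd_sqrt(Omega)
                gamma_vec = ws.gamma(Gamma_new)
                B, c, r = _batched_solve(
                    ws, v, np.array([tau]), beta[None, :], gamma_vec
                )
                moved = np.abs(B[0] - beta).max()
                beta = B[0]
                if Gamma is not None and moved < tol and np.abs(Gamma_new - Gamma).max() < tol:
                    Gamma = Gamma_new
                    break
                Gamma = Gamma_new
            field.beta[iv, it] = beta
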