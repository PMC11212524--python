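"""Cumulative coefficients and per-subject influence functions.

The cumulative coefficient B̂_τ(v) = ∫_a^v β̂_τ(u) du converges weakly at
the parametric n^{1/2} rate; its limiting covariance is driven by two
per-subject influence terms,

    φ̂1i(v,τ) = ∫_a^v Â_τ(u)⁻¹ η̂_i(u,τ) du            (estimating score)
    φ̂2i(v,τ) = ∫_a^v Â_τ(u)⁻¹ r̂_i(u,τ) du            (IPCW correction)

with r̂_i(u,τ) = ∫_0^L ω̂_τ(s,u) Ȳ(s)⁻¹ dM̂_i^C(s) the integral of the
kernel-localized at-risk functional ω̂ against subject i's censoring
martingale.  The covariance estimator is the Gram average

    Ψ̂(v1,v2,τ1,τ2) = n⁻¹ Σ_i [φ̂1i(v1,τ1)φ̂1i(v2,τ2)'
                               + φ̂2i(v1,τ1)φ̂2i(v2,τ2)'].

The first term of the theoretical φ1 involves the marked point measure
N_i(dt,du); the empirical version realizes it with the kernel-localized
atom K_h(V_i − u), the same localization used by ω̂ and by the efficacy
influence ϑ̂0i, so every "hat" quantity is computable from data with one
convention.  All mark integrals use the trapezoidal rule on the grid.
"""

from __future__ import annotations

import numpy as np

from .data import MarkQRError
from .estimation import CoefficientField
from .variance import PointwiseCovariance, pointwise_covariance

__all__ = [
    "cumulative_beta",
    "omega_fn",
    "InfluenceSet",
    "influence_set",
    "psi_hat",
]


def cumulative_beta(field: CoefficientField, strict: bool = True) -> np.ndarray:
    """B̂_τ(v) = ∫_a^v β̂_τ(u) du on the grid (trapezoid); B̂_τ(a) = 0.

    With ``strict`` an unconverged cell anywhere in the integration range
    raises, listing the offending cells; otherwise NaNs propagate.
    """
    if strict and field.n_unconverged:
        bad = np.argwhere(~field.converged)
        raise MarkQRError(
            f"cumulative_beta over unconverged cells (iv, it): {bad.tolist()[:20]}"
        )
    marks = field.grid.mark_points
    return _cumtrapz(field.beta, marks, axis=0)


def _cumtrapz(y: np.ndarray, x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Cumulative trapezoid along ``axis``, starting at 0."""
    y = np.moveaxis(y, axis, 0)
    dx = np.diff(x).reshape((-1,) + (1,) * (y.ndim - 1))
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * dx * (y[1:] + y[:-1]), axis=0)
    return np.moveaxis(out, 0, axis)


# ---------------------------------------------------------------------------
# ω̂ and the censoring-martingale integrals
# ---------------------------------------------------------------------------

def omega_fn(
    s: float,
    u: float,
    field: CoefficientField,
    tau_index: int = 0,
) -> np.ndarray:
    """ω̂_τ(s, u): kernel-weighted IPCW mean of Z over events in [s, Q̂].

    ω̂_τ(s,u) = n⁻¹ Σ_i Δ_i I(X_i ≤ L) Z_i I[s ≤ X_i ≤ H{Z_i'β̂_τ(u)}]
                K_h(V_i − u) Ĝ(X_i-)⁻¹,

    nonincreasing in s componentwise for nonnegative covariates and zero
    beyond the follow-up horizon.
    """
    ws = field.workspace
    marks = field.grid.mark_points
    iu = int(np.argmin(np.abs(marks - u)))
    if abs(marks[iu] - u) < 1e-12:
        beta = field.beta[iu, tau_index]
    else:
        beta = field.beta_at_mark(u, tau_index)
    idx, Za, ya, wa = ws.cell_arrays(u)
    if idx.size == 0:
        return np.zeros(ws.q)
    upper = field.link.forward(Za @ beta)
    keep = (s <= ws.X[idx]) & (ws.X[idx] <= upper)
    return (Za[keep] * wa[keep, None]).sum(axis=0) / ws.n


class _CensoringCache:
    """Per-mark-point structures for the martingale integrals of φ̂2.

    Everything that does not depend on τ is precomputed once: the window
    events sorted by time, the censoring times (truncated at L) with their
    Nelson–Aalen increments and at-risk levels, each subject's count of
    censoring times up to X_i, and each censored subject's own jump index.
    """

    def __init__(self, field: CoefficientField):
        ws = field.workspace
        cm = field.censoring
        L = field.grid.horizon
        keep = cm.censor_times <= L
        self.s_cens = cm.censor_times[keep]
        self.dLam = cm.dLambda[keep]
        self.Ybar = cm.Ybar_at_censor[keep]
        if np.any(self.Ybar <= 0.0):
            raise MarkQRError("Ȳ(s) = 0 at a censoring time ≤ L; lower the horizon")
        self.m_c = self.s_cens.size
        # subjects: compensator extent and own jump position
        self.cnt = np.searchsorted(self.s_cens, ws.X, side="right")
        self.is_cens = (ws.delta == 0.0) & (ws.X <= L)
        self.jump_pos = np.searchsorted(self.s_cens, ws.X[self.is_cens])
        self.ws = ws
        self.field = field
        self._per_u: dict[int, tuple] = {}

    def _u_struct(self, iu: int):
        cached = self._per_u.get(iu)
        if cached is not None:
            return cached
        ws = self.ws
        v = self.field.grid.mark_points[iu]
        idx, Za, ya, wa = ws.cell_arrays(v)
        order = np.argsort(ws.X[idx], kind="stable")
        idx = idx[order]
        Xs = ws.X[idx]
        contrib = ws.Z[idx] * wa[order, None]  # Z_k K_h Ĝ⁻¹, sorted by time
        pos = np.searchsorted(Xs, self.s_cens, side="left")
        out = (idx, Xs, contrib, pos)
        self._per_u[iu] = out
        return out

    def omega_at_censor_times(self, iu: int, it: int) -> np.ndarray:
        """ω̂(s_j, u) for all censoring times s_j ≤ L: shape (m_c, q)."""
        idx, Xs, contrib, pos = self._u_struct(iu)
        ws = self.ws
        if idx.size == 0 or self.m_c == 0:
            return np.zeros((self.m_c, ws.q))
        beta = self.field.beta[iu, it]
        upper = self.field.link.forward(ws.Z[idx] @ beta)
        kept = np.where((Xs <= upper)[:, None], contrib, 0.0)
        suffix = np.vstack([np.cumsum(kept[::-1], axis=0)[::-1], np.zeros(ws.q)])
        return suffix[pos] / ws.n

    def r_full(self, iu: int, it: int) -> np.ndarray:
        """r̂_i(u,τ) = ∫ ω̂ Ȳ⁻¹ dM̂_i^C for all subjects: shape (n, q)."""
        ws = self.ws
        if self.m_c == 0:
            return np.zeros((ws.n, ws.q))
        R = self.omega_at_censor_times(iu, it) / self.Ybar[:, None]
        comp = np.vstack([np.zeros(ws.q), np.cumsum(R * self.dLam[:, None], axis=0)])
        out = -comp[self.cnt]
        out[self.is_cens] += R[self.jump_pos]
        return out

    def r_projected(self, iu: int, it: int, a_vec: np.ndarray) -> np.ndarray:
        """a'r̂_i(u,τ) for all subjects (scalar per subject)."""
        ws = self.ws
        if self.m_c == 0:
            return np.zeros(ws.n)
        Rp = self.omega_at_censor_times(iu, it) @ a_vec / self.Ybar
        comp = np.concatenate([[0.0], np.cumsum(Rp * self.dLam)])
        out = -comp[self.cnt]
        out[self.is_cens] += Rp[self.jump_pos]
        return out

    def r_projected_batch(self, iu: int, beta_u: np.ndarray, a_vecs: np.ndarray,
                          link) -> np.ndarray:
        """a_τ'r̂_i(u,τ) for all subjects and all τ at once: shape (nt, n).

        ``beta_u`` is (nt, q) and ``a_vecs`` (nt, q); the suffix-sum over
        events and the compensator cumulative sum are shared across τ.
        """
        ws = self.ws
        nt = beta_u.shape[0]
        if self.m_c == 0:
            return np.zeros((nt, ws.n))
        idx, Xs, contrib, pos = self._u_struct(iu)
        if idx.size == 0:
            return np.zeros((nt, ws.n))
        upper = link.forward(ws.Z[idx] @ beta_u.T)  # (m, nt)
        kproj = (contrib @ a_vecs.T) * (Xs[:, None] <= upper)  # (m, nt)
        suffix = np.vstack([np.cumsum(kproj[::-1], axis=0)[::-1], np.zeros(nt)])
        R = suffix[pos] / (ws.n * self.Ybar[:, None])  # (m_c, nt)
        comp = np.vstack([np.zeros(nt), np.cumsum(R * self.dLam[:, None], axis=0)])
        out = -comp[self.cnt]  # (n, nt)
        out[self.is_cens] += R[self.jump_pos]
        return out.T


# ---------------------------------------------------------------------------
# influence set
# ---------------------------------------------------------------------------

class InfluenceSet:
    """Per-subject influence functions φ̂1i, φ̂2i over the grid (lazy).

    Built from a fitted :class:`CoefficientField` and its pointwise
    covariance; matrices are computed per (v, τ) cell on demand.
    """

    def __init__(self, field: CoefficientField, cov: PointwiseCovariance | None = None):
        self.field = field
        self.cov = cov if cov is not None else pointwise_covariance(field)
        self.cache = _CensoringCache(field)

    # -- per-u densities -------------------------------------------------
    def score_density(self, iu: int, it: int) -> np.ndarray:
        """Â(u)⁻¹ η̂_i(u,τ) for all subjects: the u-density of φ̂1i."""
        ws = self.field.workspace
        Ai = self.cov.A_inv[iu, it]
        if not np.all(np.isfinite(Ai)):
            raise MarkQRError(f"Â not invertible at cell (iu={iu}, it={it})")
        from .variance import _cell_eta_weights

        g = _cell_eta_weights(self.field, iu, it)
        return (ws.Z @ Ai.T) * g[:, None]

    def censor_density(self, iu: int, it: int) -> np.ndarray:
        """Â(u)⁻¹ r̂_i(u,τ): the u-density of φ̂2i."""
        Ai = self.cov.A_inv[iu, it]
        if not np.all(np.isfinite(Ai)):
            raise MarkQRError(f"Â not invertible at cell (iu={iu}, it={it})")
        return self.cache.r_full(iu, it) @ Ai.T

    # -- integrated influences -------------------------------------------
    def _integrated(self, iv: int, it: int, which: str) -> np.ndarray:
        marks = self.field.grid.mark_points[: iv + 1]
        ws = self.field.workspace
        acc = np.zeros((ws.n, ws.q))
        if iv == 0:
            return acc
        prev = None
        for k, u in enumerate(marks):
            dens = (
                self.score_density(k, it)
                if which == "phi1"
                else self.censor_density(k, it)
            )
            if prev is not None:
                acc += 0.5 * (marks[k] - marks[k - 1]) * (dens + prev)
            prev = dens
        return acc

    def phi1_matrix(self, iv: int, it: int) -> np.ndarray:
        """φ̂1i(v,τ) for all subjects: shape (n, p+1); zero at v = a."""
        return self._integrated(iv, it, "phi1")

    def phi2_matrix(self, iv: int, it: int) -> np.ndarray:
        """φ̂2i(v,τ) for all subjects: shape (n, p+1); zero at v = a."""
        return self._integrated(iv, it, "phi2")

    def phi1(self, i: int, iv: int, it: int) -> np.ndarray:
        return self.phi1_matrix(iv, it)[i]

    def phi2(self, i: int, iv: int, it: int) -> np.ndarray:
        return self.phi2_matrix(iv, it)[i]

    def B_hat(self, strict: bool = True) -> np.ndarray:
        return cumulative_beta(self.field, strict=strict)

    # -- covariance -------------------------------------------------------
    def _locate(self, v: float, tau: float) -> tuple[int, int]:
        grid = self.field.grid
        iv = int(np.argmin(np.abs(grid.mark_points - v)))
        it = int(np.argmin(np.abs(grid.tau_points - tau)))
        if abs(grid.mark_points[iv] - v) > 1e-9 or abs(grid.tau_points[it] - tau) > 1e-9:
            raise MarkQRError(f"(v={v}, tau={tau}) is not a grid node")
        return iv, it

    def psi(self, v1: float, v2: float, tau1: float, tau2: float) -> np.ndarray:
        """Ψ̂(v1,v2,τ1,τ2): covariance of n^{1/2}{B̂_τ1(v1), B̂_τ2(v2)}."""
        iv1, it1 = self._locate(v1, tau1)
        iv2, it2 = self._locate(v2, tau2)
        p1a, p2a = self.phi1_matrix(iv1, it1), self.phi2_matrix(iv1, it1)
        p1b, p2b = self.phi1_matrix(iv2, it2), self.phi2_matrix(iv2, it2)
        n = self.field.workspace.n
        return (p1a.T @ p1b + p2a.T @ p2b) / n


def influence_set(field: CoefficientField, cov: PointwiseCovariance | None = None) -> InfluenceSet:
    """Build the lazy per-subject influence evaluator."""
    return InfluenceSet(field, cov)


def psi_hat(infl: InfluenceSet, v1: float, v2: float, tau1: float, tau2: float) -> np.ndarray:
    """Functional form of :meth:`InfluenceSet.psi`."""
    return infl.psi(v1, v2, tau1, tau2)
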