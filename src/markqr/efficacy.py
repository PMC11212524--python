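"""Mark-specific quantile-type vaccine efficacy: curves, tests, bands.

With the treatment indicator as the first covariate, the log-linear model
gives qve_τ(v) = exp{β̂1τ(v)} − 1: the relative lengthening, under vaccine,
of the time by which a fraction τ of mark-v infections has accrued.  Its
mark-cumulative version cqve_τ(v) = ∫_a^v qve_τ(u) du and the further
quantile-cumulative ccqve_τ(v) = ∫_{τ0}^τ cqve_s(v) ds aggregate the
efficacy over mark and quantile ranges and converge at the n^{1/2} rate.

Hypotheses:

* H10: qve_τ(v) ≡ 0 on [a,b]×[τ0,τU] (no efficacy), tested by the
  sup-integral statistic T11 and the directional end-point statistic
  T12(τ); T12 is standard-normal calibrated, T11 is calibrated by Gaussian
  multiplier resampling of the per-subject influence ϑ̂0i.
* H20: qve_τ(v) ≡ ψ (constant efficacy), tested by the sup statistic T21
  (multiplier calibrated) and the monotone-trend statistic T22(τ)
  (standard-normal calibrated), both built from scaled contrasts of ccqve
  and cqve against their full-range averages.

The per-subject influence of n^{1/2}cqvê_τ(v) is

    ϑ̂0i(τ,v) = −∫_a^v exp{β̂1τ(u)} e1' Â_τ(u)⁻¹
                 [η̂_i(u,τ) + r̂_i(u,τ)] du,

the delta-method image of the φ̂1 + φ̂2 influence densities of the
cumulative coefficient, and ζ̂0τ(v) = n⁻¹Σϑ̂0i² estimates the variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import ndtr, ndtri

from .cumulative import _CensoringCache, _cumtrapz
from .data import MarkQRError
from .estimation import CoefficientField
from .variance import PointwiseCovariance, _cell_eta_weights, pointwise_covariance

__all__ = [
    "EfficacyCurves",
    "TestReport",
    "qve_curves",
    "theta0",
    "test_H10",
    "test_H20",
    "confidence_bands",
]


@dataclass
class EfficacyCurves:
    """Efficacy surfaces and their per-subject influence arrays.

    ``qve``/``cqve``/``ccqve`` have shape (n_mark, n_tau); ``theta0`` has
    shape (n, n_mark, n_tau); ``zeta0`` = n⁻¹Σϑ̂0i² matches qve's grid.
    ``treatment_coef`` is the index of the treatment coefficient in the
    design vector (1 = first covariate, the default trial layout).
    """

    field: CoefficientField
    cov: PointwiseCovariance
    treatment_coef: int
    qve: np.ndarray
    cqve: np.ndarray
    ccqve: np.ndarray
    theta0: np.ndarray
    zeta0: np.ndarray

    @property
    def grid(self):
        return self.field.grid

    @property
    def n(self) -> int:
        return self.field.workspace.n

    # θ1/θ2 are cheap derivations; cached lazily
    _theta1: np.ndarray | None = dc_field(default=None, repr=False)
    _sub_v: np.ndarray | None = dc_field(default=None, repr=False)
    _sub_t: np.ndarray | None = dc_field(default=None, repr=False)

    def subgrid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Grid indices with v ≥ a1 and τ ≥ τ0* (the constancy-test region)."""
        if self._sub_v is None:
            g = self.grid
            self._sub_v = np.flatnonzero(g.mark_points >= g.inner_mark_start - 1e-12)
            self._sub_t = np.flatnonzero(g.tau_points >= g.inner_tau_start - 1e-12)
        return self._sub_v, self._sub_t

    def theta1(self) -> np.ndarray:
        """ϑ̂1i on the inner subgrid: shape (n, |v ≥ a1|, |τ ≥ τ0*|)."""
        if self._theta1 is None:
            g = self.grid
            iv_sub, it_sub = self.subgrid_indices()
            Theta = _cumtrapz(self.theta0, g.tau_points, axis=2)  # ∫_{τ0}^τ ϑ0 ds
            va = g.mark_points[iv_sub] - g.a
            ta = g.tau_points[it_sub] - g.tau0
            denom = va[None, :, None] * ta[None, None, :]
            ref = Theta[:, -1, -1] / ((g.b - g.a) * (g.tauU - g.tau0))
            self._theta1 = Theta[:, iv_sub][:, :, it_sub] / denom - ref[:, None, None]
        return self._theta1

    def theta2(self) -> np.ndarray:
        """ϑ̂2i(τ) for every τ node: shape (n, n_tau).

        The reference term uses ϑ̂0i(τ, b) — the influence of the
        cqve_τ(b)/(b−a) offset that T22(τ)'s own numerator subtracts — so
        the positive correlation between the two terms cancels in ζ̂2
        exactly as it does in the statistic.
        """
        g = self.grid
        iv_sub, _ = self.subgrid_indices()
        v_sub = g.mark_points[iv_sub]
        ratio = self.theta0[:, iv_sub, :] / (v_sub - g.a)[None, :, None]
        ref = self.theta0[:, -1, :] / (g.b - g.a)  # ϑ̂0i(τ, b) per τ
        integ = np.trapezoid(ratio, v_sub, axis=1)
        return integ - (g.b - g.mark_points[iv_sub[0]]) * ref


def qve_curves(
    field: CoefficientField,
    cov: PointwiseCovariance | None = None,
    treatment_coef: int = 1,
) -> EfficacyCurves:
    """Compute qve/cqve/ccqve and the influence arrays from a fitted field."""
    if field.link.name != "exp":
        raise MarkQRError("vaccine-efficacy functionals require the log link")
    if not (1 <= treatment_coef <= field.data.p):
        raise MarkQRError(
            f"treatment_coef={treatment_coef} is not a covariate coefficient "
            f"(design has {field.data.p} covariates)"
        )
    if cov is None:
        cov = pointwise_covariance(field)
    ws = field.workspace
    g = field.grid
    nv, nt = g.n_mark, g.n_tau
    beta1 = field.beta[:, :, treatment_coef]
    with np.errstate(over="ignore"):  # diverged (flagged) cells may overflow
        qve = np.exp(beta1) - 1.0
    cqve = _cumtrapz(qve, g.mark_points, axis=0)
    ccqve = _cumtrapz(cqve, g.tau_points, axis=1) if nt > 1 else np.zeros_like(cqve)

    cache = _CensoringCache(field)
    if not np.all(np.isfinite(cov.A_inv)):
        bad = np.argwhere(~np.isfinite(cov.A_inv[:, :, 0, 0]))
        raise MarkQRError(
            f"Â not invertible at grid cells (iv, it) {bad.tolist()[:10]}; "
            "cannot form ϑ̂0i"
        )
    taus = g.tau_points
    dens = np.empty((nv, nt, ws.n))
    for iu, v in enumerate(g.mark_points):
        a_vecs = cov.A_inv[iu, :, :, treatment_coef]  # Â⁻¹e1 per τ, (nt, q)
        idx, Za, ya, wa = ws.cell_arrays(v)
        gmat = np.broadcast_to(-taus[:, None], (nt, ws.n)).copy()
        if idx.size:
            gmat[:, idx] += wa[None, :] * (ya[None, :] <= field.beta[iu] @ Za.T)
        proj = (ws.Z @ a_vecs.T).T * gmat  # e1'Â⁻¹η̂_i, (nt, n)
        proj += cache.r_projected_batch(iu, field.beta[iu], a_vecs, field.link)
        dens[iu] = np.exp(beta1[iu])[:, None] * proj
    theta0 = np.ascontiguousarray(
        np.moveaxis(-_cumtrapz(dens, g.mark_points, axis=0), 2, 0)
    )
    zeta0 = np.mean(theta0 * theta0, axis=0)
    return EfficacyCurves(
        field=field, cov=cov, treatment_coef=treatment_coef,
        qve=qve, cqve=cqve, ccqve=ccqve, theta0=theta0, zeta0=zeta0,
    )


def theta0(curves: EfficacyCurves, i: int, iv: int, it: int) -> float:
    """ϑ̂0i at one subject and grid cell (ϑ̂0i(·, a) = 0)."""
    return float(curves.theta0[i, iv, it])


# ---------------------------------------------------------------------------
# test reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestReport:
    """One test statistic with its calibration."""

    name: str
    statistic: float
    critical_value: float
    p_value: float
    alpha: float
    calibration: str  # "normal" or "multiplier"
    n_resamples: int = 0
    tau: float | None = None

    @property
    def reject(self) -> bool:
        return self.statistic > self.critical_value

    def as_dict(self) -> dict:
        d = {
            "name": self.name, "statistic": self.statistic,
            "critical_value": self.critical_value, "p_value": self.p_value,
            "alpha": self.alpha, "calibration": self.calibration,
            "n_resamples": self.n_resamples, "reject": self.reject,
        }
        if self.tau is not None:
            d["tau"] = self.tau
        return d


def _check_zeta(z: np.ndarray, label: str) -> None:
    if np.any(~np.isfinite(z)) or np.any(z <= 0.0):
        raise MarkQRError(f"degenerate variance {label} (zero or non-finite)")


def _t11_functional(num_sq: np.ndarray, zeta0: np.ndarray, marks: np.ndarray) -> np.ndarray:
    """∫_a^b num²/ζ0 dv then sup over τ; num_sq has shape (..., nv, nt).

    Both numerator and ζ0 vanish at v = a at the same quadratic rate, so
    the integrand at the boundary node is set to its limit from the first
    interior node.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num_sq / zeta0
    ratio[..., 0, :] = ratio[..., 1, :]
    integral = np.trapezoid(ratio, marks, axis=-2)
    return integral.max(axis=-1)


def test_H10(
    curves: EfficacyCurves,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Test H10: no efficacy anywhere on the (mark, quantile) region.

    Returns ``{"T11": TestReport, "T12": [TestReport per τ node],
    "reject_joint": bool, "T11_resamples": draws}``.  T11's critical value
    is the (1−α) quantile of B Gaussian-multiplier draws; T12 is one-sided
    standard normal.
    """
    g = curves.grid
    n = curves.n
    _check_zeta(curves.zeta0[1:, :], "ζ̂0 (interior)")
    T11 = float(_t11_functional(n * curves.cqve**2, curves.zeta0, g.mark_points))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W = rng.standard_normal((B, n))
    Gp = (W @ curves.theta0.reshape(n, -1)).reshape(B, g.n_mark, g.n_tau) / np.sqrt(n)
    draws = _t11_functional(Gp**2, curves.zeta0[None], g.mark_points)
    c11 = float(np.quantile(draws, 1.0 - alpha))
    p11 = float((1 + np.sum(draws >= T11)) / (B + 1))
    rep11 = TestReport("T11", T11, c11, p11, alpha, "multiplier", B)

    z_a = float(ndtri(1.0 - alpha))
    reps12 = []
    for it, tau in enumerate(g.tau_points):
        t12 = float(np.sqrt(n) * curves.cqve[-1, it] / np.sqrt(curves.zeta0[-1, it]))
        reps12.append(TestReport(
            "T12", t12, z_a, float(1.0 - ndtr(t12)), alpha, "normal", tau=float(tau)
        ))
    return {
        "T11": rep11,
        "T12": reps12,
        "reject_joint": rep11.reject and any(r.reject for r in reps12),
        "T11_resamples": draws,
    }


def test_H20(
    curves: EfficacyCurves,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    statistics: tuple = ("T21", "T22"),
) -> dict:
    """Test H20: efficacy constant in the mark.

    T21 is the sup over the inner subgrid [a1,b]×[τ0*,τU] of the
    standardized contrast of scaled ccqve against its full-range average
    (multiplier calibrated); T22(τ) is the normal-calibrated monotone-trend
    statistic.  ``statistics`` restricts the computation: T22 alone needs
    no resampling and no quantile-cumulative curves.
    """
    g = curves.grid
    n = curves.n
    out: dict = {}
    if "T22" in statistics:
        out.update(_t22_reports(curves, alpha))
    if "T21" not in statistics:
        out["reject_joint"] = None
        return out
    iv_sub, it_sub = curves.subgrid_indices()
    v_sub = g.mark_points[iv_sub]
    t_sub = g.tau_points[it_sub]

    theta1 = curves.theta1()
    zeta1 = np.mean(theta1**2, axis=0)
    # at (v, τ) = (b, τU) the contrast and its influence vanish identically
    # (the cell is compared with itself); the 0/0 cell contributes 0
    valid = zeta1 > 0.0
    if np.any(~np.isfinite(zeta1)) or np.any(np.abs(theta1).max(axis=0)[~valid] > 0.0):
        raise MarkQRError("degenerate variance ζ̂1 (zero or non-finite)")
    scale = (v_sub[:, None] - g.a) * (t_sub[None, :] - g.tau0)
    ref = curves.ccqve[-1, -1] / ((g.b - g.a) * (g.tauU - g.tau0))
    contrast = curves.ccqve[iv_sub][:, it_sub] / scale - ref
    with np.errstate(divide="ignore", invalid="ignore"):
        T21_surface = np.where(valid, np.sqrt(n) * contrast / np.sqrt(zeta1), 0.0)
    T21 = float(np.abs(T21_surface).max())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W = rng.standard_normal((B, n))
    Gp = (W @ theta1.reshape(n, -1)).reshape(B, v_sub.size, t_sub.size) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        std_draws = np.where(valid[None], Gp / np.sqrt(zeta1)[None], 0.0)
    draws = np.abs(std_draws).max(axis=(1, 2))
    c21 = float(np.quantile(draws, 1.0 - alpha))
    p21 = float((1 + np.sum(draws >= T21)) / (B + 1))
    rep21 = TestReport("T21", T21, c21, p21, alpha, "multiplier", B)

    out["T21"] = rep21
    out["T21_resamples"] = draws
    if "T22" in statistics:
        out["reject_joint"] = rep21.reject and any(r.reject for r in out["T22"])
    else:
        out["reject_joint"] = rep21.reject
    return out


def _t22_reports(curves: EfficacyCurves, alpha: float) -> dict:
    """Normal-calibrated monotone-trend statistics T22(τ), every τ node."""
    g = curves.grid
    n = curves.n
    iv_sub, _ = curves.subgrid_indices()
    v_sub = g.mark_points[iv_sub]
    theta2 = curves.theta2()
    zeta2 = np.mean(theta2**2, axis=0)
    _check_zeta(zeta2, "ζ̂2")
    ratio = curves.cqve[iv_sub, :] / (v_sub - g.a)[:, None]
    endpoint = curves.cqve[-1, :] / (g.b - g.a)
    integ = np.trapezoid(ratio - endpoint[None, :], v_sub, axis=0)
    z_a = float(ndtri(1.0 - alpha))
    reps22 = []
    for it, tau in enumerate(g.tau_points):
        t22 = float(np.sqrt(n) * integ[it] / np.sqrt(zeta2[it]))
        reps22.append(TestReport(
            "T22", t22, z_a, float(1.0 - ndtr(t22)), alpha, "normal", tau=float(tau)
        ))
    return {"T22": reps22}


# ---------------------------------------------------------------------------
# confidence bands
# ---------------------------------------------------------------------------

def confidence_bands(
    curves: EfficacyCurves,
    level: float = 0.95,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    kind: str = "pointwise",
    target: str = "cqve",
):
    """Pointwise intervals or simultaneous-in-v bands for qve or cqve.

    Pointwise: cqve ± z_{α/2}(ζ̂0/n)^{1/2}; qve ± z_{α/2}exp(β̂1)
    (Ω̂_11/(nh))^{1/2} (delta method).  Simultaneous (per τ): the pointwise
    SE is scaled by the (1−α) multiplier quantile of
    sup_v |n^{-1/2}ΣW_iϑ̂0i(τ,v)|/ζ̂0^{1/2}(v), so the band contains the
    pointwise interval at every node.  Returns a tidy DataFrame.
    """
    import pandas as pd

    if not (0.0 < level < 1.0):
        raise MarkQRError("confidence level must be in (0, 1)")
    if kind not in ("pointwise", "simultaneous"):
        raise MarkQRError("kind must be 'pointwise' or 'simultaneous'")
    if target not in ("qve", "cqve"):
        raise MarkQRError("target must be 'qve' or 'cqve'")
    g = curves.grid
    n = curves.n
    alpha = 1.0 - level
    z = float(ndtri(1.0 - alpha / 2.0))
    if target == "cqve":
        center = curves.cqve
        se = np.sqrt(curves.zeta0 / n)
    else:
        center = curves.qve
        beta1 = curves.field.beta[:, :, curves.treatment_coef]
        se = np.exp(beta1) * curves.cov.se(curves.treatment_coef)

    if kind == "pointwise":
        mult = np.full(g.n_tau, z)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        W = rng.standard_normal((B, n))
        Gp = (W @ curves.theta0.reshape(n, -1)).reshape(B, g.n_mark, g.n_tau) / np.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            std = np.abs(Gp) / np.sqrt(curves.zeta0)[None]
        std[:, 0, :] = std[:, 1, :]
        sup_draws = std.max(axis=1)  # (B, n_tau)
        mult = np.quantile(sup_draws, level, axis=0)
        mult = np.maximum(mult, z)  # simultaneous never narrower than pointwise

    vv, tt = np.meshgrid(g.mark_points, g.tau_points, indexing="ij")
    half = mult[None, :] * se
    return pd.DataFrame({
        "v": vv.ravel(), "tau": tt.ravel(), "target": target, "kind": kind,
        "estimate": center.ravel(),
        "lower": (center - half).ravel(),
        "upper": (center + half).ravel(),
        "se": se.ravel(),
    })
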