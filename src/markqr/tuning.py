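"""Bandwidth selection and quantile-range diagnostics.

Two bandwidth selectors are provided:

* M-fold cross-validation minimizing a prediction error built on the
  model identity E[∫_a^v ∫_0^L I{log s ≤ Z'β*_τ(u)} G(s|Z)⁻¹ N(ds,du) | Z]
  = τ(v − a): with β̂ fitted on the training folds, a test subject's
  IPCW-weighted exceedance profile should track τ(v − a), and PE is the
  squared deviation integrated over the (mark, quantile) region.
* The rule of thumb h = ϖ σ̂_V n0^{-1/4}, with σ̂_V the standard
  deviation of the observed marks and n0 the number of events.

A stratified mark-specific cumulative incidence estimator F̂_v(t|Z=z)
supports choosing the upper quantile level: τU must stay below
min_{v,z} max_t F̂_v(t|Z=z) for the localized quantile to be identified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .censoring import fit_censoring
from .data import EvaluationGrid, MarkedSurvivalDataset, MarkQRError
from .estimation import fit_field

__all__ = [
    "BandwidthSelection",
    "cv_bandwidth",
    "rule_of_thumb_h",
    "incidence_estimate",
    "tau_upper_limit",
]

DEFAULT_CANDIDATES = (0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass(frozen=True)
class BandwidthSelection:
    """Cross-validation result: total PE per candidate and the argmin."""

    candidates: tuple[float, ...]
    pe: np.ndarray  # total prediction error per candidate (inf if flagged)
    pe_by_fold: np.ndarray  # (n_candidates, M)
    h_opt: float
    folds: int
    seed: int | None
    flagged: tuple[bool, ...]  # True where a training fit had empty windows


def _stratified_folds(status: np.ndarray, M: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels balanced on event status (sizes within ±1 per stratum)."""
    fold = np.empty(status.size, dtype=int)
    for val in (0.0, 1.0):
        idx = np.flatnonzero(status == val)
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % M
    return fold


def _subset(data: MarkedSurvivalDataset, mask: np.ndarray) -> MarkedSurvivalDataset:
    return MarkedSurvivalDataset(
        time=data.time[mask],
        status=data.status[mask],
        mark=data.mark[mask],
        covariates=data.covariates[mask],
        covariate_names=data.covariate_names,
    )


def cv_bandwidth(
    data: MarkedSurvivalDataset,
    grid_template: EvaluationGrid,
    candidates=DEFAULT_CANDIDATES,
    M: int = 5,
    seed: int | None = None,
    g_weighting: str = "divide",
) -> BandwidthSelection:
    """Choose the bandwidth by M-fold cross-validated prediction error.

    For each candidate h and fold k, β̂^{(-k)} is fitted on the other
    folds with bandwidth h; the fold-k prediction error is

        PE_k(h) = Σ_{i∈D_k} ∫∫ [ m̂_i(v,τ) − τ(v − a) ]² dv dτ,

    where m̂_i(v,τ) = Δ_i I(X_i ≤ L) I(a ≤ V_i ≤ v)
    I{log X_i ≤ Z_i'β̂^{(-k)}_τ(V_i)} / Ĝ^{(-k)}(X_i-).  The inner mark
    integral runs over [a, v] (the fitted range) against the target
    τ(v − a); ``g_weighting="literal"`` multiplies by Ĝ instead of
    dividing (the uncorrected reading of the weight).
    """
    if M < 2:
        raise MarkQRError("cross-validation needs at least 2 folds")
    if g_weighting not in ("divide", "literal"):
        raise MarkQRError("g_weighting must be 'divide' or 'literal'")
    candidates = tuple(float(h) for h in candidates)
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(data.status, M, rng)
    grid = grid_template
    marks, taus = grid.mark_points, grid.tau_points
    a = grid.a
    target = taus[:, None] * (marks[None, :] - a)  # (nt, nv)
    base_pe = np.trapezoid(np.trapezoid(target**2, marks, axis=1), taus)

    pe_by_fold = np.zeros((len(candidates), M))
    flagged = [False] * len(candidates)
    for k in range(M):
        train = _subset(data, fold != k)
        test_mask = fold == k
        test = _subset(data, test_mask)
        cens = fit_censoring(train)
        for ci, h in enumerate(candidates):
            if flagged[ci]:
                continue
            try:
                fld = fit_field(train, cens, grid.with_bandwidth(h),
                                warn_threshold=1.1)
            except MarkQRError:
                flagged[ci] = True
                continue
            if np.isnan(fld.beta).any():
                # an empty kernel window in a training fold: no estimate
                # exists there, so the candidate is flagged, not skipped
                flagged[ci] = True
                continue
            pe_by_fold[ci, k] = _fold_pe(
                test, fld, cens, marks, taus, target, base_pe, g_weighting
            )
    pe = pe_by_fold.sum(axis=1)
    pe = np.where(flagged, np.inf, pe)
    if not np.any(np.isfinite(pe)):
        raise MarkQRError("every candidate bandwidth was flagged; enlarge the data or h grid")
    h_opt = candidates[int(np.argmin(pe))]
    return BandwidthSelection(
        candidates=candidates, pe=pe, pe_by_fold=pe_by_fold, h_opt=h_opt,
        folds=M, seed=seed, flagged=tuple(flagged),
    )


def _fold_pe(test, fld, cens, marks, taus, target, base_pe, g_weighting) -> float:
    """PE contribution of one test fold under one fitted field."""
    L = fld.grid.horizon
    ev = (test.status == 1.0) & (test.time <= L) & np.isfinite(test.mark)
    ev &= (test.mark >= marks[0]) & (test.mark <= marks[-1])
    n_passive = test.n - int(ev.sum())  # censored / out-of-range: m̂_i ≡ 0
    total = n_passive * base_pe
    if not ev.any():
        return float(total)
    Vi = test.mark[ev]
    Zi = np.column_stack([np.ones(ev.sum()), test.covariates[ev]])
    yi = np.log(test.time[ev])
    Gm = cens.G_minus(test.time[ev])
    wi = Gm if g_weighting == "literal" else 1.0 / Gm
    # β̂_τ(V_i) by linear interpolation along the mark grid
    pos = np.clip(np.searchsorted(marks, Vi) - 1, 0, marks.size - 2)
    lam = (Vi - marks[pos]) / (marks[pos + 1] - marks[pos])
    beta_at_V = (1 - lam)[:, None, None] * fld.beta[pos] + lam[:, None, None] * fld.beta[pos + 1]
    fitted = np.einsum("itq,iq->it", beta_at_V, Zi)  # (n_ev, nt)
    c = (yi[:, None] <= fitted).astype(float) * wi[:, None]  # m̂ level once v ≥ V_i
    step = (Vi[:, None] <= marks[None, :]).astype(float)  # (n_ev, nv)
    resid = c[:, :, None] * step[:, None, :] - target[None]  # (n_ev, nt, nv)
    total += np.trapezoid(np.trapezoid(resid**2, marks, axis=2), taus, axis=1).sum()
    return float(total)


def rule_of_thumb_h(data: MarkedSurvivalDataset, varpi: float = 1.0) -> float:
    """Rule-of-thumb bandwidth h = ϖ σ̂_V n0^{-1/4}."""
    obs = data.observed_marks()
    n0 = obs.size
    if n0 < 2:
        raise MarkQRError("rule-of-thumb bandwidth needs at least 2 observed events")
    return float(varpi * np.std(obs, ddof=1) * n0 ** (-0.25))


def incidence_estimate(
    data: MarkedSurvivalDataset,
    censoring=None,
    stratum: np.ndarray | None = None,
    t: float = np.inf,
    v: float = 0.5,
    h: float = 0.2,
    kernel=None,
    conditional: bool = False,
) -> float:
    """Stratified kernel-smoothed IPCW mark-specific cumulative incidence.

    F̂_v(t|Z=z) = n⁻¹ Σ_i I(Z_i = z) Δ_i I(X_i ≤ t) K_h(V_i − v)/Ĝ(X_i-);
    ``stratum`` is a boolean subject mask defining {Z_i = z} (all subjects
    when None).  ``conditional`` divides by the stratum fraction to yield
    a conditional rather than joint subdistribution.  Nondecreasing in t.
    """
    from .data import KernelSpec

    if censoring is None:
        censoring = fit_censoring(data)
    if stratum is None:
        stratum = np.ones(data.n, bool)
    stratum = np.asarray(stratum, bool)
    if not stratum.any():
        raise MarkQRError("empty covariate stratum")
    kern = kernel or KernelSpec()
    sel = stratum & (data.status == 1.0) & (data.time <= t)
    if not sel.any():
        return 0.0
    w = kern.scaled(data.mark[sel], v, h) / censoring.G_minus(data.time[sel])
    out = float(w.sum() / data.n)
    if conditional:
        out *= data.n / stratum.sum()
    return out


def tau_upper_limit(
    data: MarkedSurvivalDataset,
    strata: list[np.ndarray],
    mark_values: np.ndarray,
    h: float = 0.2,
    censoring=None,
    kernel=None,
) -> float:
    """Admissible upper quantile level: min over (v, stratum) of
    max_t F̂_v(t|Z=z); τU should be chosen strictly below this value."""
    if censoring is None:
        censoring = fit_censoring(data)
    t_max = float(np.max(data.time))
    vals = [
        incidence_estimate(data, censoring, z, t_max, v, h, kernel)
        for z in strata
        for v in np.atleast_1d(mark_values)
    ]
    return float(np.min(vals))
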