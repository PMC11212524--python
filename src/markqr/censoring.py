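"""Censoring-distribution machinery.

Inverse-probability-of-censoring weighting (IPCW) needs the survival
function G(t) = P(C ≥ t) of the censoring time, estimated by Kaplan–Meier
with Δ = 0 treated as the event, together with the Nelson–Aalen cumulative
hazard Λ̂_C, the at-risk proportion Ȳ(s) and per-subject censoring
martingale residuals M̂_i^C(s) = I(X_i ≤ s, Δ_i = 0) − ∫_0^s Y_i dΛ̂_C.
The residuals feed the censoring-adjustment term of the influence
functions; Σ_i M̂_i^C(s) = 0 holds exactly at every s by construction.

The counting quantities come from lifelines' Kaplan–Meier event table; the
step functions are assembled here so that left limits and compensator
increments are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .data import MarkedSurvivalDataset, MarkQRError

__all__ = ["CensoringModel", "fit_censoring", "censoring_martingale"]


@dataclass(frozen=True)
class CensoringModel:
    """Step-function summaries of the censoring distribution.

    Attributes
    ----------
    times
        Sorted distinct observed times (all X_i, event or censored).
    censor_times
        Sorted distinct times with at least one censoring.
    G_steps
        Ĝ(t) evaluated at ``times`` (right-continuous product-limit value).
    Lambda_steps
        Λ̂_C(t) at ``times`` (Nelson–Aalen).
    dLambda
        Increment dΛ̂_C at each ``censor_times`` entry: dN^C / (n Ȳ).
    Ybar_at_censor
        Ȳ(s) = n⁻¹ Σ I(X_i ≥ s) at each ``censor_times`` entry.
    n
        Sample size the model was fitted on.
    """

    times: np.ndarray
    censor_times: np.ndarray
    G_steps: np.ndarray
    Lambda_steps: np.ndarray
    dLambda: np.ndarray
    Ybar_at_censor: np.ndarray
    n: int

    # -- evaluators ------------------------------------------------------
    def G(self, t) -> np.ndarray:
        """Right-continuous Ĝ(t); Ĝ(0) = 1."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        out = np.where(idx >= 0, self.G_steps[np.clip(idx, 0, None)], 1.0)
        return out if np.ndim(t) else float(out)

    def G_minus(self, t) -> np.ndarray:
        """Left limit Ĝ(t-): the censoring survival just before t.

        IPCW weights use 1/Ĝ(X-) so a subject's own censoring hazard at X
        never enters its weight.
        """
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left") - 1
        out = np.where(idx >= 0, self.G_steps[np.clip(idx, 0, None)], 1.0)
        return out if np.ndim(t) else float(out)

    def Lambda(self, t) -> np.ndarray:
        """Nelson–Aalen Λ̂_C(t), right-continuous."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        out = np.where(idx >= 0, self.Lambda_steps[np.clip(idx, 0, None)], 0.0)
        return out if np.ndim(t) else float(out)

    def Ybar(self, s) -> np.ndarray:
        """At-risk proportion Ȳ(s) = n⁻¹ Σ I(X_i ≥ s)."""
        # times is sorted; number with X_i >= s via searchsorted on all times
        counts = self._at_risk_counts
        idx = np.searchsorted(self.times, np.asarray(s, dtype=float), side="left")
        out = np.where(idx < self.times.size, counts[np.clip(idx, 0, counts.size - 1)], 0.0) / self.n
        return out if np.ndim(s) else float(out)

    @property
    def _at_risk_counts(self) -> np.ndarray:
        # subjects at risk at each distinct time (computed once, cached)
        if not hasattr(self, "_arc"):
            object.__setattr__(self, "_arc", np.cumsum(self._multiplicity[::-1])[::-1])
        return self._arc

    def martingale(self, time: float, status: float, s) -> np.ndarray:
        """Censoring martingale residual M̂^C(s) for a subject (X, Δ).

        M̂^C(s) = I(X ≤ s, Δ = 0) − Λ̂_C(min(s, X)).
        """
        s_arr = np.asarray(s, dtype=float)
        if np.any(s_arr < 0):
            raise MarkQRError("martingale time s must be nonnegative")
        jump = ((time <= s_arr) & (status == 0)).astype(float)
        comp = self.Lambda(np.minimum(s_arr, time))
        out = jump - comp
        return out if np.ndim(s) else float(out)

    def export_G(self) -> np.ndarray:
        """Two-column table (t, Ĝ(t)) of the step function, for debugging."""
        return np.column_stack([self.times, self.G_steps])


def fit_censoring(data: MarkedSurvivalDataset) -> CensoringModel:
    """Kaplan–Meier / Nelson–Aalen fit of the censoring distribution.

    Censorings are the "events" here (Δ = 0).  With tied failure and
    censoring times, failures precede censorings in the risk-set accounting:
    the at-risk set at t is {X_i ≥ t} for both processes, the standard
    survival convention.
    """
    if data.n == 0:
        raise MarkQRError("cannot fit a censoring model on empty data")
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=1.0 - data.status)
    table = kmf.event_table  # indexed by distinct times, with counts
    times = table.index.to_numpy(dtype=float)
    if times[0] == 0.0 and table["observed"].iloc[0] == 0 and table["censored"].iloc[0] == 0:
        table = table.iloc[1:]
        times = times[1:]
    at_risk = table["at_risk"].to_numpy(dtype=float)
    d_cens = table["observed"].to_numpy(dtype=float)  # censorings (our "events")
    multiplicity = (table["observed"] + table["censored"]).to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(at_risk > 0, d_cens / at_risk, 0.0)
    G_steps = np.cumprod(1.0 - frac)
    Lambda_steps = np.cumsum(frac)

    has_cens = d_cens > 0
    model = CensoringModel(
        times=times,
        censor_times=times[has_cens],
        G_steps=G_steps,
        Lambda_steps=Lambda_steps,
        dLambda=frac[has_cens],
        Ybar_at_censor=at_risk[has_cens] / data.n,
        n=data.n,
    )
    object.__setattr__(model, "_multiplicity", multiplicity)
    return model


def censoring_martingale(model: CensoringModel, time: float, status: float, s):
    """Functional form of :meth:`CensoringModel.martingale`."""
    return model.martingale(time, status, s)


def check_positivity(model: CensoringModel, horizon: float) -> None:
    """Abort if Ĝ(t-) = 0 for some t ≤ L (IPCW positivity violated)."""
    if model.G_minus(horizon) <= 0.0:
        raise MarkQRError(
            f"Ĝ(t-) reaches 0 before the follow-up horizon L = {horizon:g}; "
            "lower L (or raise eps_g) so inverse-censoring weights stay bounded"
        )
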