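"""Core data containers: marked survival datasets, kernels, evaluation grids.

A *marked* survival record is the competing-risks quadruple (X, Δ, ΔV, Z̃):
observed time X = min(T, C), event indicator Δ = I(T ≤ C), a continuous mark
V ∈ [0, 1] recorded only when the failure is observed (for an HIV vaccine
trial, V is the genetic distance between the infecting virus and the vaccine
insert), and a covariate vector Z̃ of length p.  The design vector is
Z = (1, Z̃')' of length p + 1.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkedSurvivalDataset",
    "KernelSpec",
    "EvaluationGrid",
    "read_dataset",
    "write_dataset",
    "kernel_weight",
    "build_grid",
]


class MarkQRError(ValueError):
    """Base class for validation and parameter errors."""


@dataclass(frozen=True)
class MarkedSurvivalDataset:
    """Subject-level data for mark-specific quantile regression.

    Parameters
    ----------
    time
        Observed times X_i > 0 (log-time is modelled, so nonpositive times
        are rejected).
    status
        Event indicators Δ_i ∈ {0, 1}; 1 means the failure was observed.
    mark
        Marks V_i, present (finite) exactly where ``status == 1`` and NaN on
        censored rows.
    covariates
        n × p matrix Z̃ of covariates, without the intercept.
    covariate_names
        Optional column labels for reporting; defaults to z1..zp.
    mark_rescaling
        If the marks were affinely rescaled to [0, 1] on ingestion, the
        (lo, hi) pair of the original observed-mark range; None otherwise.
    """

    time: np.ndarray
    status: np.ndarray
    mark: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...] = ()
    mark_rescaling: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        time = np.ascontiguousarray(np.asarray(self.time, dtype=float))
        status = np.ascontiguousarray(np.asarray(self.status, dtype=float))
        mark = np.ascontiguousarray(np.asarray(self.mark, dtype=float))
        cov = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if cov.shape[0] != time.shape[0] and cov.shape[1] == time.shape[0]:
            cov = cov.T
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "mark", mark)
        object.__setattr__(self, "covariates", np.ascontiguousarray(cov))
        n = time.shape[0]
        if status.shape != (n,) or mark.shape != (n,) or cov.shape[0] != n:
            raise MarkQRError("time, status, mark and covariates disagree in length")
        if not np.all(np.isin(status, (0.0, 1.0))):
            raise MarkQRError("status must be 0/1")
        if np.any(~np.isfinite(time)) or np.any(time <= 0.0):
            bad = np.flatnonzero(~(np.isfinite(time) & (time > 0.0)))
            raise MarkQRError(f"nonpositive or non-finite time at rows {bad.tolist()}")
        events = status == 1.0
        missing = events & ~np.isfinite(mark)
        if np.any(missing):
            raise MarkQRError(
                "missing mark on event rows "
                f"{np.flatnonzero(missing).tolist()}; marks are required whenever "
                "status == 1 (subjects with unknown marks must be handled upstream)"
            )
        stray = ~events & np.isfinite(mark)
        if np.any(stray):
            warnings.warn(
                f"mark present on censored rows {np.flatnonzero(stray).tolist()}; "
                "dropped (the mark is undefined when the failure is censored)",
                stacklevel=2,
            )
            mark = mark.copy()
            mark[stray] = np.nan
            object.__setattr__(self, "mark", mark)
        obs = mark[events]
        if obs.size and (obs.min() < 0.0 or obs.max() > 1.0):
            raise MarkQRError(
                "marks must lie in [0, 1]; pass rescale_mark=True on ingestion "
                f"(observed range [{obs.min():.4g}, {obs.max():.4g}])"
            )
        if not self.covariate_names:
            object.__setattr__(
                self,
                "covariate_names",
                tuple(f"z{j + 1}" for j in range(cov.shape[1])),
            )

    # -- derived views ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def design(self) -> np.ndarray:
        """Design matrix Z = (1, Z̃) of shape (n, p + 1)."""
        return np.column_stack([np.ones(self.n), self.covariates])

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def observed_marks(self) -> np.ndarray:
        """Marks of the uncensored subjects."""
        return self.mark[self.status == 1.0]

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.time, "status": self.status.astype(int), "mark": self.mark}
        for j, name in enumerate(self.covariate_names):
            cols[name] = self.covariates[:, j]
        return pd.DataFrame(cols)


_DEFAULT_SCHEMA = {"time": "time", "status": "status", "mark": "mark"}


def read_dataset(
    path,
    schema: dict | None = None,
    covariate_columns: list[str] | None = None,
    rescale_mark: bool = False,
) -> MarkedSurvivalDataset:
    """Read a delimited text file into a :class:`MarkedSurvivalDataset`.

    ``schema`` maps the roles ``time``/``status``/``mark`` to column names;
    every remaining column is treated as a covariate unless
    ``covariate_columns`` narrows the choice.  Missing marks may be encoded
    as empty fields or NA tokens.  With ``rescale_mark`` the observed event
    marks are mapped affinely from their sample range onto [0, 1] and the
    original range is recorded on the dataset.
    """
    frame = pd.read_csv(path)
    names = dict(_DEFAULT_SCHEMA)
    if schema:
        names.update(schema)
    for role, col in names.items():
        if col not in frame.columns:
            raise MarkQRError(f"column {col!r} (role {role!r}) not found in {path}")
    if covariate_columns is None:
        covariate_columns = [c for c in frame.columns if c not in names.values()]
    missing = [c for c in covariate_columns if c not in frame.columns]
    if missing:
        raise MarkQRError(f"covariate columns {missing} not found in {path}")

    time = frame[names["time"]].to_numpy(dtype=float)
    status = frame[names["status"]].to_numpy(dtype=float)
    mark = frame[names["mark"]].to_numpy(dtype=float)
    rescaling = None
    if rescale_mark:
        obs = mark[status == 1.0]
        obs = obs[np.isfinite(obs)]
        if obs.size < 2 or obs.max() == obs.min():
            raise MarkQRError("rescale_mark needs at least two distinct event marks")
        lo, hi = float(obs.min()), float(obs.max())
        mark = (mark - lo) / (hi - lo)
        rescaling = (lo, hi)
    return MarkedSurvivalDataset(
        time=time,
        status=status,
        mark=mark,
        covariates=frame[covariate_columns].to_numpy(dtype=float),
        covariate_names=tuple(covariate_columns),
        mark_rescaling=rescaling,
    )


def write_dataset(data: MarkedSurvivalDataset, path) -> None:
    """Write the dataset as CSV (empty field for undefined marks)."""
    data.to_frame().to_csv(path, index=False)


def dataset_from_csv_text(text: str, **kwargs) -> MarkedSurvivalDataset:
    """Parse CSV content given as a string (convenience for small examples)."""
    return read_dataset(io.StringIO(text), **kwargs)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _epanechnikov(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(np.abs(x) < 1.0, 0.75 * (1.0 - x * x), 0.0)


def _triweight(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    inside = np.abs(x) < 1.0
    return np.where(inside, (35.0 / 32.0) * (1.0 - x * x) ** 3, 0.0)


def _uniform(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(np.abs(x) < 1.0, 0.5, 0.0)


_KERNELS = {
    # name -> (K, ∫u²K(u)du, ν0 = ∫K(u)²du)
    "epanechnikov": (_epanechnikov, 0.2, 0.6),
    "triweight": (_triweight, 1.0 / 9.0, 350.0 / 429.0),
    "uniform": (_uniform, 1.0 / 3.0, 0.5),
}


@dataclass(frozen=True)
class KernelSpec:
    """A symmetric density kernel on [-1, 1].

    The default is the Epanechnikov kernel K(x) = 0.75(1 - x²)I(|x| < 1),
    with roughness ν0 = ∫K² = 0.6.
    """

    name: str = "epanechnikov"

    def __post_init__(self) -> None:
        if self.name not in _KERNELS:
            raise MarkQRError(f"unknown kernel {self.name!r}; choose from {sorted(_KERNELS)}")

    def __call__(self, x) -> np.ndarray:
        return _KERNELS[self.name][0](x)

    @property
    def second_moment(self) -> float:
        return _KERNELS[self.name][1]

    @property
    def nu0(self) -> float:
        """Kernel roughness ∫K(u)²du, entering the asymptotic variance."""
        return _KERNELS[self.name][2]

    def scaled(self, u, v, h: float) -> np.ndarray:
        """K_h(u - v) = K((u - v)/h)/h."""
        if h <= 0:
            raise MarkQRError("bandwidth h must be positive")
        return self((np.asarray(u, dtype=float) - v) / h) / h


def kernel_weight(u, v, h: float, kernel: KernelSpec | None = None) -> np.ndarray:
    """Localizing weight K_h(u - v); zero whenever |u - v| ≥ h."""
    return (kernel or KernelSpec()).scaled(u, v, h)


# ---------------------------------------------------------------------------
# evaluation grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationGrid:
    """Mark × quantile evaluation grid with smoothing bandwidth.

    The analysis is restricted to marks v ∈ [a, b] ⊂ (0, 1) and quantile
    levels τ ∈ [τ0, τU]; ``inner_mark_start`` (a1) and ``inner_tau_start``
    (τ0*) delimit the inner subregion used by the sup-type constancy test.
    ``horizon`` is the follow-up time L with P(X ≥ L) > 0.
    """

    mark_points: np.ndarray
    tau_points: np.ndarray
    bandwidth: float
    horizon: float
    inner_mark_start: float
    inner_tau_start: float
    kernel: KernelSpec = field(default_factory=KernelSpec)

    def __post_init__(self) -> None:
        mark = np.ascontiguousarray(np.asarray(self.mark_points, dtype=float))
        tau = np.ascontiguousarray(np.asarray(self.tau_points, dtype=float))
        object.__setattr__(self, "mark_points", mark)
        object.__setattr__(self, "tau_points", tau)
        if mark.ndim != 1 or mark.size < 2 or np.any(np.diff(mark) <= 0):
            raise MarkQRError("mark_points must be strictly increasing, length ≥ 2")
        if tau.ndim != 1 or tau.size < 1 or np.any(np.diff(tau) <= 0):
            raise MarkQRError("tau_points must be strictly increasing")
        a, b = mark[0], mark[-1]
        if not (0.0 < a < b < 1.0):
            raise MarkQRError("mark range must satisfy 0 < a < b < 1")
        if not (0.0 < tau[0] <= tau[-1] < 1.0):
            raise MarkQRError("quantile range must lie inside (0, 1)")
        if self.bandwidth <= 0:
            raise MarkQRError("bandwidth h must be positive")
        if self.horizon <= 0:
            raise MarkQRError("horizon L must be positive")
        if not (a < self.inner_mark_start < b):
            raise MarkQRError("inner_mark_start a1 must satisfy a < a1 < b")
        if tau.size > 1 and not (tau[0] < self.inner_tau_start < tau[-1]):
            raise MarkQRError("inner_tau_start τ0* must satisfy τ0 < τ0* < τU")
        if a - self.bandwidth < 0.0 or b + self.bandwidth > 1.0:
            warnings.warn(
                f"kernel support escapes the mark support [0, 1]: "
                f"[a - h, b + h] = [{a - self.bandwidth:.3g}, {b + self.bandwidth:.3g}]; "
                "no boundary correction is applied",
                stacklevel=2,
            )

    @property
    def a(self) -> float:
        return float(self.mark_points[0])

    @property
    def b(self) -> float:
        return float(self.mark_points[-1])

    @property
    def tau0(self) -> float:
        return float(self.tau_points[0])

    @property
    def tauU(self) -> float:
        return float(self.tau_points[-1])

    @property
    def n_mark(self) -> int:
        return self.mark_points.size

    @property
    def n_tau(self) -> int:
        return self.tau_points.size

    def with_horizon(self, horizon: float) -> "EvaluationGrid":
        return EvaluationGrid(
            self.mark_points, self.tau_points, self.bandwidth, horizon,
            self.inner_mark_start, self.inner_tau_start, self.kernel,
        )

    def with_bandwidth(self, h: float) -> "EvaluationGrid":
        return EvaluationGrid(
            self.mark_points, self.tau_points, h, self.horizon,
            self.inner_mark_start, self.inner_tau_start, self.kernel,
        )


def default_horizon(data: MarkedSurvivalDataset, eps_g: float = 0.05) -> float:
    """Largest event time t with Ĝ(t-) ≥ eps_g.

    Keeps the inverse-censoring weights 1/Ĝ(X-) bounded by 1/eps_g; the
    user may override by passing an explicit horizon.
    """
    from .censoring import fit_censoring  # local import to avoid a cycle

    model = fit_censoring(data)
    event_times = np.sort(data.time[data.status == 1.0])
    ok = model.G_minus(event_times) >= eps_g
    if not np.any(ok):
        raise MarkQRError(
            "no event time has Ĝ(t-) ≥ eps_g; censoring is too heavy for the "
            "requested positivity margin"
        )
    return float(event_times[ok][-1])


def build_grid(
    a: float = 0.3,
    b: float = 0.8,
    tau0: float = 0.1,
    tauU: float = 0.4,
    n_mark: int = 50,
    n_tau: int = 50,
    h: float = 0.2,
    horizon: float | MarkedSurvivalDataset | None = None,
    inner_mark_start: float | None = None,
    inner_tau_start: float | None = None,
    kernel: KernelSpec | None = None,
    eps_g: float = 0.05,
) -> EvaluationGrid:
    """Build an evenly spaced :class:`EvaluationGrid`.

    ``horizon`` may be an explicit L, or a dataset, in which case L defaults
    to the largest event time with Ĝ(t-) ≥ ``eps_g``.  Defaults follow the
    standard simulation design: 50 evenly spaced points on [0.3, 0.8] and
    [0.1, 0.4], a1 = 0.35, τ0* = 0.15.
    """
    if not (a < b) or not (tau0 <= tauU):
        raise MarkQRError("inverted ranges: need a < b and tau0 <= tauU")
    if isinstance(horizon, MarkedSurvivalDataset):
        horizon = default_horizon(horizon, eps_g=eps_g)
    elif horizon is None:
        horizon = float("inf")  # resolved against data by the fitting entry points
    if inner_mark_start is None:
        inner_mark_start = a + 0.1 * (b - a)
    if inner_tau_start is None:
        inner_tau_start = tau0 + (tauU - tau0) / 6.0 if tauU > tau0 else tau0
    mark = np.linspace(a, b, n_mark)
    tau = np.linspace(tau0, tauU, n_tau) if n_tau > 1 else np.array([tau0])
    return EvaluationGrid(
        mark_points=mark,
        tau_points=tau,
        bandwidth=h,
        horizon=horizon,
        inner_mark_start=inner_mark_start,
        inner_tau_start=inner_tau_start,
        kernel=kernel or KernelSpec(),
    )
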