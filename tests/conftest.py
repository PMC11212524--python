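"""Shared fixtures: small synthetic datasets and fitted objects.

Expensive fits are session-scoped so that estimation, variance, influence
and efficacy tests reuse one fitted field.
"""

from __future__ import annotations

import numpy as np
import pytest

from markqr.data import MarkedSurvivalDataset, build_grid
from markqr.estimation import fit_field
from markqr.simulate import design, generate
from markqr.variance import pointwise_covariance


@pytest.fixture()
def tiny_dataset() -> MarkedSurvivalDataset:
    """Three subjects, two events — the smallest legal dataset."""
    return MarkedSurvivalDataset(
        time=np.array([1.0, 2.0, 3.0]),
        status=np.array([1.0, 0.0, 1.0]),
        mark=np.array([0.4, np.nan, 0.6]),
        covariates=np.array([[0.0], [1.0], [1.0]]),
    )


def single_observation_dataset(t0: float = 2.0, mark: float = 0.5) -> MarkedSurvivalDataset:
    """One uncensored intercept-only subject (p = 0)."""
    return MarkedSurvivalDataset(
        time=np.array([t0]),
        status=np.array([1.0]),
        mark=np.array([mark]),
        covariates=np.empty((1, 0)),
    )


@pytest.fixture(scope="session")
def m2_data() -> MarkedSurvivalDataset:
    """One M2 draw (constant efficacy, ~40% censoring), n = 600."""
    return generate(design("M2", n=600), seed=314)


@pytest.fixture(scope="session")
def m2_grid(m2_data):
    """Coarse 12x8 grid on the standard region (keeps unit tests fast)."""
    return build_grid(n_mark=12, n_tau=8, h=0.2, horizon=m2_data)


@pytest.fixture(scope="session")
def m2_field(m2_data, m2_grid):
    return fit_field(m2_data, None, m2_grid)


@pytest.fixture(scope="session")
def m2_cov(m2_field):
    return pointwise_covariance(m2_field)
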