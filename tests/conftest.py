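"""Shared fixtures: deterministic AIFs and small synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

from myoflow.curves import DynamicCurve
from myoflow.synthetic import AIFParams, gamma_variate_aif


@pytest.fixture(scope="session")
def times_1s() -> np.ndarray:
    """The default acquisition grid: 50 frames at 1 s spacing."""
    return np.arange(50, dtype=float)


@pytest.fixture(scope="session")
def aif_curve(times_1s) -> DynamicCurve:
    """Default stress gamma-variate AIF on the 1 s grid."""
    return gamma_variate_aif(AIFParams(), times_1s)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
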