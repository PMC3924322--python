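"""Shared fixtures: small deterministic series generators."""

from __future__ import annotations

import numpy as np
import pytest

from neuroais.datatypes import EpochedSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ar1(phi: float, n: int, seed: int, sd_innov: float = 1.0) -> np.ndarray:
    """Gaussian AR(1) realization started from the stationary distribution."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd_innov / np.sqrt(1.0 - phi**2)) if abs(phi) < 1 else 0.0
    eps = rng.normal(0.0, sd_innov, n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


@pytest.fixture
def ar1_series():
    return make_ar1


@pytest.fixture
def white_noise_epochs(rng):
    return EpochedSeries(rng.standard_normal((20, 300)), sampling_rate=300.0)
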