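"""Shared fixtures: small SL parameter sets and planted synthetic data."""

from __future__ import annotations

import numpy as np
import pytest

from slnets import CouplingSchedule, SLParams, get_band
from slnets.pipeline import _planted_topographies


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Small recurrence windows for fast SL computation in tests."""
    return SLParams(l=1, m=5, w1=10, w2=59, n_rec=5)


@pytest.fixture
def broadband_params_500():
    from slnets import derive_sl_params

    return derive_sl_params(get_band("broadband"), 500.0)


@pytest.fixture
def desk_band_params_250():
    """Broadband parameters at 250 Hz with a reduced recurrence window."""
    from slnets import derive_sl_params

    return derive_sl_params(get_band("broadband"), 250.0, n_rec=10, p_ref=0.1)


def planted_vectors(seed: int, t: int = 200, n_edges: int = 45, noise: float = 0.05):
    """SL-like vectors from 3 well-separated planted clusters, contiguous in time."""
    rng = np.random.default_rng(seed)
    protos = np.zeros((3, n_edges))
    for k in range(3):
        protos[k, k * 10 : (k + 1) * 10] = 0.6
    labels = np.repeat([0, 1, 2], [70, 60, 70])[:t]
    return protos[labels] + noise * rng.random((t, n_edges)), labels


def switching_schedule(seed: int, n_channels: int = 9, durations=(420, 420, 410)):
    """Three-state coupling schedule over disjoint triple topographies."""
    topos = _planted_topographies(n_channels, 3, 1.0)
    return CouplingSchedule(
        segments=[(d, topos[i]) for i, d in enumerate(durations)],
        n_channels=n_channels,
        seed=seed,
    )
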