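"""Shared fixtures: small synthetic recordings and helper constructors."""

from __future__ import annotations

import numpy as np
import pytest

from pacpredict.coupling import CouplingPhaseMap, band_pair
from pacpredict.synthetic import SyntheticSpec, generate_patient


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def three_channel_spec():
    """5-minute, 3-channel recording with planted phases [0, 1, -2] rad."""
    return SyntheticSpec(
        n_channels=3,
        duration_s=300.0,
        seizure_onsets=(),
        interictal_phase=(0.0, 1.0, -2.0),
        modulation_depth=0.8,
        seed=11,
    )


@pytest.fixture(scope="session")
def three_channel_recording(three_channel_spec):
    recording, manifest = generate_patient(three_channel_spec)
    return recording, manifest


@pytest.fixture(scope="session")
def delta_lg_pair():
    return band_pair("delta", "LG", 256.0)


def make_phase_map(phi_c, concentration=None, window_s=60.0):
    """Construct a CouplingPhaseMap directly from a phase array."""
    phi_c = np.atleast_2d(np.asarray(phi_c, dtype=float))
    if concentration is None:
        concentration = np.where(np.isfinite(phi_c), 0.8, 0.0)
    return CouplingPhaseMap(
        phi_c=phi_c,
        concentration=np.asarray(concentration, dtype=float),
        pair=band_pair("delta", "LG", 256.0),
        window_s=window_s,
        channel_labels=[f"ch{i:03d}" for i in range(phi_c.shape[0])],
    )


@pytest.fixture
def phase_map_factory():
    return make_phase_map
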