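"""Shared fixtures: small reference models and datasets built at test time."""

import os

os.environ.setdefault("MPLBACKEND", "Agg")

import numpy as np
import pytest

from dcmident import (
    DCMModel,
    DesignSpec,
    ProfileSettings,
    Stimulus,
    load_fixture,
)


@pytest.fixture(scope="session")
def forward_fixture():
    return load_fixture("forward")


@pytest.fixture(scope="session")
def forward_short_design(forward_fixture):
    """Forward fixture design shortened to 40 volumes (two stimulus cycles)."""
    import dataclasses

    from dcmident.sweep import vary_session

    return vary_session(
        dataclasses.replace(forward_fixture.default_design), 40
    )


def make_two_region_model() -> DCMModel:
    """Two regions, one driving input, 4 free parameters (2 self, 1 coupling,
    1 driving gain).  Lower-triangular A keeps it unconditionally stable."""
    return DCMModel(
        region_names=["R1", "R2"],
        a_mask=np.array([[1.0, 0.0], [1.0, 1.0]]),
        a_values=np.array([[-0.6, 0.0], [0.4, -0.6]]),
        b_masks=np.zeros((1, 2, 2)),
        b_values=np.zeros((1, 2, 2)),
        c_mask=np.array([[1.0], [0.0]]),
        c_values=np.array([[0.8], [0.0]]),
        input_names=["Stim"],
    )


def make_two_region_design() -> DesignSpec:
    """300 s session, TR 2 s, 4 slices: 7 boxcar epochs of 20 s every 40 s."""
    train = tuple(Stimulus(10.0 + 40.0 * k, 20.0) for k in range(7))
    return DesignSpec(
        tr=2.0, n_slices=4, n_volumes=150, stimuli=(train,),
        input_names=("Stim",),
    )


@pytest.fixture(scope="session")
def two_region_model():
    return make_two_region_model()


@pytest.fixture(scope="session")
def two_region_design():
    return make_two_region_design()


@pytest.fixture(scope="session")
def fast_settings():
    """Reduced profile budget used by the heavier end-to-end checks."""
    return ProfileSettings(max_steps=15)
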