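"""Shared fixtures: default models and session-scoped expensive artifacts."""

import numpy as np
import pytest

from phasorph import simulate
from phasorph.phasor import IRFModel
from phasorph.pipeline import (
    calibration_acquisition,
    live_acquisition,
    run_titration,
)


@pytest.fixture(scope="session")
def sensor():
    return simulate.SensorModel()


@pytest.fixture(scope="session")
def irf():
    return IRFModel(center=1.0, sigma=0.15)


@pytest.fixture(scope="session")
def acq_small():
    """Small uniform-field acquisition for fast phasor-level tests."""
    return simulate.AcquisitionParams(
        n_bins=64, frame_shape=(64, 64), target_median_counts=200.0
    )


@pytest.fixture(scope="session")
def acq_live():
    return live_acquisition()


@pytest.fixture(scope="session")
def acq_cal():
    return calibration_acquisition()


@pytest.fixture(scope="session")
def titration():
    """One full synthetic titration shared by downstream tests."""
    return run_titration(seed=123)


@pytest.fixture(scope="session")
def landscape_scene():
    return simulate.make_scene(
        simulate.landscape_populations(), seed=7, shape=(256, 256)
    )


@pytest.fixture(scope="session")
def landscape_stack(landscape_scene, sensor, irf, acq_live):
    return simulate.render_decay_stack(
        landscape_scene, sensor, irf, acq_live, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
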