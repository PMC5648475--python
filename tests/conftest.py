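import numpy as np
import pytest

from aqueflow.phantoms import (
    CohortSimConfig,
    GroupSimConfig,
    WomersleyPhantomSpec,
    womersley_velocity,
)


@pytest.fixture(scope="session")
def study_spec():
    """Womersley phantom at the study's gating on a grid fine enough to
    resolve the tube: R = 2 mm, 60 bpm, 32 phases, 0.5 mm voxels."""
    return WomersleyPhantomSpec(
        tube_radius=2.0,
        heart_rate=60.0,
        n_cardiac_phases=32,
        voxel_size=0.5,
        grid_shape=(24, 24, 10),
        pressure_gradient_amplitude=100.0,
    )


@pytest.fixture(scope="session")
def study_phantom(study_spec):
    return womersley_velocity(study_spec)


@pytest.fixture
def tiny_cohort_config():
    """Reduced-size cohort for fast end-to-end runs."""
    return CohortSimConfig(
        groups={
            "control": GroupSimConfig(n=2, pg_amplitude_median=100.0, venc=5.0),
            "iNPH": GroupSimConfig(n=2, pg_amplitude_median=354.5, harmonic=4, venc=30.0),
            "AD": GroupSimConfig(n=2, pg_amplitude_median=354.5, harmonic=4, venc=30.0),
        },
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
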