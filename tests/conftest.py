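import numpy as np
import pytest

from memblm import (
    DriveSpec,
    MembraneParams,
    SyntheticSpec,
    generate_trace,
    integrate_to_steady_state,
    reference_parameter_sets,
)


@pytest.fixture(scope="session")
def refs():
    return reference_parameter_sets()


@pytest.fixture(scope="session")
def azolectin(refs):
    """The azolectin membrane set and its 200 mV / 1 Hz drive."""
    r = refs["azolectin_200mV_1Hz"]
    return r.params, r.drive


@pytest.fixture(scope="session")
def azolectin_trace(azolectin):
    """Noiseless 25-period 1 kHz synthetic recording of the azolectin set."""
    params, drive = azolectin
    return generate_trace(
        SyntheticSpec(params=params, drive=drive, noise_sd=0.0, seed=7)
    )

@pytest.fixture(scope="session")
def azolectin_steady(azolectin):
    params, drive = azolectin
    return integrate_to_steady_state(params, drive)


@pytest.fixture
def linear_params():
    """A plain RC membrane: no nonlinearity, no conductance."""
    return MembraneParams(C0=1e-9, beta=0.0, kappa=0.2, tau=15e-3)


@pytest.fixture
def drive_200mV_1Hz():
    return DriveSpec(Umax=0.2, f=1.0)
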