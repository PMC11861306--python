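import numpy as np
import pytest

from fourccr import FatigueParameters, JOINT_TABLE, experiment_protocol
from fourccr.synthetic_data import DEFAULT_CENTRAL, default_study_specs


@pytest.fixture(scope="session")
def central():
    """Synthetic ground-truth central-side constants (FC0, RC0, r, L)."""
    return dict(DEFAULT_CENTRAL)


@pytest.fixture(scope="session")
def sf_params(central):
    """Shoulder-flexor-style full parameter set (fitted velocity split +
    synthetic central constants)."""
    return FatigueParameters(
        FC0=central["FC0"], RC0=central["RC0"], r=central["r"], L=central["L"],
        k=0.0086, RP0=1.2e-5, FP0=1211 * 1.2e-5, muscle_group="shoulder_flexors",
    )


@pytest.fixture(scope="session")
def study_specs():
    return default_study_specs()


@pytest.fixture(scope="session")
def knee_protocol():
    return experiment_protocol(JOINT_TABLE["knee"], 90.0)


@pytest.fixture(scope="session")
def shoulder_protocols():
    joint = JOINT_TABLE["shoulder"]
    return {v: experiment_protocol(joint, v) for v in joint.velocities}


def random_state(rng: np.random.Generator):
    """A valid random compartment state (Dirichlet keeps the sum at 1)."""
    from fourccr import CompartmentState

    m = rng.dirichlet(np.ones(4))
    m = m / m.sum()
    return CompartmentState(MA=m[0], MR=m[1], MFP=m[2], MFC=m[3])
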