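import numpy as np
import pytest

from csfbc.boundary_conditions import build_bc, harmonic_shape
from csfbc.constitutive import FluidProperties, MaterialModel
from csfbc.solver import NetworkModel


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def material():
    return MaterialModel()


@pytest.fixture(scope="session")
def shape():
    """Canonical normalized pulsatile shape (peak at 17.5% of the cycle)."""
    return harmonic_shape()


def make_network(scheme="C", group="patient", shape=None, amplitude=1e-6, **overrides):
    """Small helper: a default NetworkModel for one scheme/group."""
    if shape is None:
        shape = harmonic_shape()
    bc = build_bc(
        scheme,
        group,
        subject_waveform=None if scheme == "A" else shape,
        pulsatile_amplitude=None if scheme == "A" else amplitude,
    )
    defaults = dict(
        V0=281.6e-6 if group == "patient" else 20.3e-6,
        aqueduct_radius=1.5e-3 if group == "patient" else 1.0e-3,
    )
    defaults.update(overrides)
    return NetworkModel(bc=bc, **defaults)


@pytest.fixture
def network_factory():
    return make_network


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
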