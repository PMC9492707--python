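import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from liqprop.sysmodel import BondedTerm, SpeciesTemplate, build_system_map
from liqprop.trajio import BoxBounds, Frame, Trajectory


@pytest.fixture
def water_template():
    return SpeciesTemplate(
        name="water",
        elements=["O", "H", "H"],
        masses=[15.999, 1.008, 1.008],
        charges=[-0.8476, 0.4238, 0.4238],
        net_charge=0.0,
        nonbond=[(0.1553, 3.166), (0.0, 0.0), (0.0, 0.0)],
        bonds=[
            BondedTerm(atoms=(0, 1), coeffs=(450.0, 1.0)),
            BondedTerm(atoms=(0, 2), coeffs=(450.0, 1.0)),
        ],
        angles=[BondedTerm(atoms=(1, 0, 2), coeffs=(55.0, 109.47))],
    )


@pytest.fixture
def ion_template():
    return SpeciesTemplate(
        name="lithium",
        elements=["Li"],
        masses=[6.94],
        charges=[1.0],
        net_charge=1.0,
        nonbond=[(0.018, 2.126)],
    )


@pytest.fixture
def neutral_ion_template():
    return SpeciesTemplate(
        name="probe", elements=["Li"], masses=[6.94], charges=[0.0]
    )


@pytest.fixture
def diatomic_template():
    return SpeciesTemplate(
        name="solv",
        elements=["O", "H"],
        masses=[15.999, 1.008],
        charges=[0.0, 0.0],
        bonds=[BondedTerm(atoms=(0, 1), coeffs=(450.0, 0.5))],
    )


def make_frame(positions, box_edge=20.0, step=0, **kwargs):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return Frame(
        step=step,
        box=BoxBounds(0, box_edge, 0, box_edge, 0, box_edge),
        ids=np.arange(1, n + 1),
        types=kwargs.pop("types", np.ones(n, dtype=int)),
        positions=positions,
        **kwargs,
    )


@pytest.fixture
def frame_factory():
    return make_frame


@pytest.fixture
def static_trajectory():
    pos = np.array([[1.0, 1.0, 1.0], [5.0, 5.0, 5.0], [9.0, 2.0, 7.0]])
    frames = [make_frame(pos, step=s) for s in range(5)]
    return Trajectory(frames=frames, unit_style="real", dt_sample=1.0)
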