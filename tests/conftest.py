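import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cspine10.constitutive import LigamentCurve
from cspine10.geometry import assemble_segment, build_segment_geometry
from cspine10.scaling import ScaleFactorSet
from cspine10.solver import Element, SegmentAssembly

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def linear_bar(
    name: str,
    stiffness: float,
    failure_deflection: float = 1e6,
    x: float = 0.0,
    length: float = 10.0,
) -> Element:
    """Vertical tension-only bar with a linear curve up to a failure deflection."""
    curve = LigamentCurve(
        points=np.array([[0.0, 0.0], [failure_deflection, stiffness * failure_deflection]]),
        failure_deflection=failure_deflection,
    )
    return Element(
        name=name,
        kind="ligament_bar",
        inferior=(x, 0.0),
        superior=(x, length),
        curve=curve,
    )


def linear_assembly(stiffnesses, failure_deflections=None, name="fixture") -> SegmentAssembly:
    if failure_deflections is None:
        failure_deflections = [1e6] * len(stiffnesses)
    elements = [
        linear_bar(f"bar{i}", k, d) for i, (k, d) in enumerate(zip(stiffnesses, failure_deflections))
    ]
    return SegmentAssembly(name=name, elements=elements)


@pytest.fixture(scope="session")
def default_sf() -> ScaleFactorSet:
    return ScaleFactorSet()


@pytest.fixture(scope="session")
def c45_geometry():
    return build_segment_geometry("C4-C5")


@pytest.fixture(scope="session")
def c67_geometry():
    return build_segment_geometry("C6-C7")


@pytest.fixture(scope="session")
def c02_geometry():
    return build_segment_geometry("C0-C2")


@pytest.fixture
def c45_assembly(c45_geometry):
    return assemble_segment(c45_geometry, disc_failure_stress=30.0, strain_increase_pct=50.0)
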