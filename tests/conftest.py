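import numpy as np
import pytest

from spherewall.geometry import SphereSpec
from spherewall.solver import FlowProblem, WallStokesOperator
from spherewall.units import ChannelSpec, FlowConditions, FluidProperties, ProfileKind

#: paper-scale configuration: 10 um sphere, 69 nm gap, 100 um channel
MU = 9e-4
GAMMADOT = 11.1


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties(MU)


@pytest.fixture(scope="session")
def channel():
    return ChannelSpec()


@pytest.fixture(scope="session")
def sphere_near_wall():
    return SphereSpec(diameter=10e-6, gap=0.069e-6)


@pytest.fixture(scope="session")
def op_near_wall_coarse(sphere_near_wall):
    """Shared coarse operator at the near-contact geometry."""
    return WallStokesOperator(sphere_near_wall, resolution="coarse")


@pytest.fixture(scope="session")
def op_near_wall_medium(sphere_near_wall):
    """Shared medium operator at the near-contact geometry."""
    return WallStokesOperator(sphere_near_wall, resolution="medium")


@pytest.fixture(scope="session")
def op_far_free():
    """Unbounded-fluid operator (images off) on an ungraded grid."""
    sp = SphereSpec(diameter=10e-6, gap=1e-3)
    return WallStokesOperator(sp, resolution="coarse", use_wall_images=False, grading=0.0)


def make_problem(fluid, channel, sphere, profile=ProfileKind.LINEAR,
                 gammadot=GAMMADOT, kinematics=(0.0, 0.0)):
    cond = FlowConditions(wss=fluid.dynamic_viscosity * gammadot, profile_kind=profile)
    return FlowProblem(fluid=fluid, channel=channel, conditions=cond,
                       sphere=sphere, kinematics=kinematics)
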