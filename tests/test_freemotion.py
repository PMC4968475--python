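import numpy as np
import pytest

from spherewall.geometry import SphereSpec
from spherewall.freemotion import (
    quasi_static_iterate,
    resistance_matrix,
    solve_free_motion,
)
from spherewall.solver import ConvectiveModeError, WallStokesOperator
from spherewall.units import ProfileKind

from conftest import GAMMADOT, MU, make_problem


@pytest.fixture(scope="module")
def rm_near_wall(fluid, channel, op_near_wall_coarse):
    prob = make_problem(fluid, channel, op_near_wall_coarse.sphere)
    return resistance_matrix(prob, operator=op_near_wall_coarse)


class TestResistanceMatrix:
    def test_drag_opposes_motion(self, rm_near_wall):
        assert rm_near_wall.is_dissipative()

    def test_reciprocal_coupling_symmetry(self, fluid, channel, op_near_wall_medium):
        """Lorentz reciprocity: force per unit rolling equals torque per
        unit translation (within 2% discretization error)."""
        prob = make_problem(fluid, channel, op_near_wall_medium.sphere)
        rm = resistance_matrix(prob, operator=op_near_wall_medium)
        assert rm.symmetry_defect() < 0.02

    def test_far_field_diagonal_limits(self, fluid, channel):
        """h >> a: the diagonal approaches the unbounded drag
        coefficients and the coupling vanishes."""
        sp = SphereSpec(diameter=10e-6, gap=50 * 5e-6)
        op = WallStokesOperator(sp, resolution="coarse")
        prob = make_problem(fluid, channel, sp, gammadot=0.0)
        rm = resistance_matrix(prob, operator=op)
        a = sp.radius
        assert rm.R[0, 0] == pytest.approx(-6 * np.pi * MU * a, rel=0.02)
        assert rm.R[1, 1] == pytest.approx(-8 * np.pi * MU * a ** 3, rel=0.02)
        coupling_scale = 6 * np.pi * MU * a ** 2
        assert abs(rm.R[0, 1]) < 0.02 * coupling_scale
        assert abs(rm.R[1, 0]) < 0.02 * coupling_scale

    def test_zero_ambient_zero_load(self, fluid, channel, op_near_wall_coarse):
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere, gammadot=0.0)
        rm = resistance_matrix(prob, operator=op_near_wall_coarse)
        assert np.abs(rm.ambient_load).max() < 1e-25

    def test_convective_mode_refused(self, fluid, channel, op_near_wall_coarse):
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere)
        from dataclasses import replace

        with pytest.raises(ConvectiveModeError):
            resistance_matrix(replace(prob, include_convective_term=True),
                              operator=op_near_wall_coarse)


class TestFreeMotion:
    def test_unbounded_shear_limit(self, fluid, channel):
        """Far from the wall the free sphere translates with the local
        ambient velocity and spins at half the shear rate."""
        sp = SphereSpec(diameter=10e-6, gap=50 * 5e-6)
        op = WallStokesOperator(sp, resolution="coarse")
        prob = make_problem(fluid, channel, sp)
        res = solve_free_motion(prob, operator=op)
        assert res.omega == pytest.approx(GAMMADOT / 2, rel=0.01)
        assert res.u == pytest.approx(GAMMADOT * sp.centre_height, rel=0.01)

    def test_residuals_below_tolerance(self, fluid, channel, rm_near_wall,
                                       op_near_wall_coarse):
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere)
        res = solve_free_motion(prob, rm=rm_near_wall)
        assert abs(res.residual_force) < 0.005 * abs(rm_near_wall.ambient_load[0])
        assert abs(res.residual_torque) < 0.005 * abs(rm_near_wall.ambient_load[1])

    def test_velocities_linear_in_wss(self, fluid, channel, rm_near_wall,
                                      op_near_wall_coarse):
        sp = op_near_wall_coarse.sphere
        r1 = solve_free_motion(make_problem(fluid, channel, sp), rm=rm_near_wall)
        r4 = solve_free_motion(
            make_problem(fluid, channel, sp, gammadot=4 * GAMMADOT), rm=rm_near_wall
        )
        assert r4.u == pytest.approx(4 * r1.u, rel=1e-9)
        assert r4.omega == pytest.approx(4 * r1.omega, rel=1e-9)

    def test_rotation_below_half_local_shear(self, fluid, channel, rm_near_wall,
                                             op_near_wall_coarse):
        """Wall hindrance: a torque-free sphere spins strictly slower
        than half the ambient shear rate."""
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere)
        res = solve_free_motion(prob, rm=rm_near_wall)
        assert 0 < res.omega < GAMMADOT / 2


class TestQuasiStaticIteration:
    def test_matches_mobility_solution(self, fluid, channel, op_near_wall_coarse,
                                       rm_near_wall):
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere)
        direct = solve_free_motion(prob, rm=rm_near_wall)
        iterated = quasi_static_iterate(prob, operator=op_near_wall_coarse)
        assert iterated.u == pytest.approx(direct.u, rel=0.005)
        assert iterated.omega == pytest.approx(direct.omega, rel=0.005)

    def test_converges_within_tens_of_steps(self, fluid, channel, op_near_wall_coarse):
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere)
        res = quasi_static_iterate(prob, operator=op_near_wall_coarse)
        assert res.iterations <= 40

    def test_exact_initial_guess_converges_immediately(self, fluid, channel,
                                                       op_near_wall_coarse,
                                                       rm_near_wall):
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere)
        direct = solve_free_motion(prob, rm=rm_near_wall)
        res = quasi_static_iterate(prob, operator=op_near_wall_coarse,
                                   initial=(direct.u, direct.omega))
        assert res.iterations <= 2
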