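import numpy as np
import pytest

from spherewall.geometry import SphereSpec, build_reduced_domain
from spherewall.solver import (
    AmbientFlow,
    FlowProblem,
    check_mass_conservation,
    domain_sensitivity,
    solve_flow,
)
from spherewall.tractions import force_torque, surface_tractions
from spherewall.units import ChannelSpec, FlowConditions, FluidProperties, ProfileKind

from conftest import GAMMADOT, MU, make_problem


class TestUnboundedOracles:
    """Closed-form Stokes results, solved with the wall images off."""

    def test_translation_drag(self, fluid, channel, op_far_free):
        U = 1e-6
        prob = make_problem(fluid, channel, op_far_free.sphere, gammadot=0.0,
                            kinematics=(U, 0.0))
        ft = force_torque(solve_flow(prob, operator=op_far_free))
        assert ft.Fx == pytest.approx(-6 * np.pi * MU * 5e-6 * U, rel=5e-3)

    def test_rotation_torque(self, fluid, channel, op_far_free):
        prob = make_problem(fluid, channel, op_far_free.sphere, gammadot=0.0,
                            kinematics=(0.0, 1.0))
        ft = force_torque(solve_flow(prob, operator=op_far_free))
        assert ft.Tz == pytest.approx(-8 * np.pi * MU * (5e-6) ** 3, rel=5e-3)

    def test_uniform_traction_of_translating_sphere(self, fluid, channel, op_far_free):
        """The exact traction is the constant -3 mu U/(2a) x_hat."""
        U = 1e-6
        prob = make_problem(fluid, channel, op_far_free.sphere, gammadot=0.0,
                            kinematics=(U, 0.0))
        tr = surface_tractions(solve_flow(prob, operator=op_far_free))
        t = tr.total()
        expected = -3 * MU * U / (2 * 5e-6)
        assert t[:, 0] == pytest.approx(expected, rel=1e-6)
        assert np.abs(t[:, 1:]).max() < 1e-6 * abs(expected)

    def test_far_field_stokes_drag_with_wall_present(self, fluid, channel):
        """Uniform inflow past a sphere far from the wall: drag within 5%
        of the unbounded closed form."""
        sp = SphereSpec(diameter=10e-6, gap=100 * 5e-6)
        from spherewall.solver import WallStokesOperator

        op = WallStokesOperator(sp, resolution="coarse")
        U = 1e-5
        prob = FlowProblem(
            fluid=fluid, channel=channel,
            conditions=FlowConditions(wss=0.0, profile_kind=ProfileKind.LINEAR),
            sphere=sp,
        )
        sol = solve_flow(prob, operator=op)
        sol.ambient = AmbientFlow.uniform(U)
        # re-solve with the uniform ambient
        from spherewall.solver import rigid_surface_velocity

        u_bc = rigid_surface_velocity(sp, (0.0, 0.0), op.nodes - op.centre)
        u_bc -= sol.ambient.velocity(op.nodes)
        sol.density = MU * op.solve_density(u_bc)
        ft = force_torque(sol)
        assert ft.Fx == pytest.approx(6 * np.pi * MU * 5e-6 * U, rel=0.05)


class TestSolveFlow:
    def test_no_sphere_returns_exact_ambient(self, fluid, channel):
        cond = FlowConditions(wss=MU * GAMMADOT, profile_kind=ProfileKind.PARABOLIC)
        prob = FlowProblem(fluid=fluid, channel=channel, conditions=cond, sphere=None)
        sol = solve_flow(prob)
        y = np.array([0.0, 10e-6, 50e-6])
        pts = np.column_stack([np.zeros(3), y, np.zeros(3)])
        expected = GAMMADOT * (y - y ** 2 / (4 * channel.half_height))
        assert sol.velocity(pts)[:, 0] == pytest.approx(expected, rel=1e-12)

    def test_zero_inflow_zero_field(self, fluid, channel, op_near_wall_coarse):
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere, gammadot=0.0)
        sol = solve_flow(prob, operator=op_near_wall_coarse)
        assert np.abs(sol.density).max() < 1e-20
        pts = np.array([[10e-6, 20e-6, 5e-6]])
        assert np.abs(sol.velocity(pts)).max() < 1e-20

    def test_direct_solve_residual_small(self, fluid, channel, op_near_wall_coarse):
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere)
        sol = solve_flow(prob, operator=op_near_wall_coarse)
        assert sol.metadata["bc_residual"] < 1e-8

    def test_linearity_in_wss(self, fluid, channel, op_near_wall_coarse):
        """Stokes mode: scaling the WSS by k scales force and torque by
        exactly k (one linear system, scaled right-hand side)."""
        p1 = make_problem(fluid, channel, op_near_wall_coarse.sphere, gammadot=GAMMADOT)
        p5 = make_problem(fluid, channel, op_near_wall_coarse.sphere, gammadot=5 * GAMMADOT)
        f1 = force_torque(solve_flow(p1, operator=op_near_wall_coarse))
        f5 = force_torque(solve_flow(p5, operator=op_near_wall_coarse))
        assert f5.Fx == pytest.approx(5 * f1.Fx, rel=1e-10)
        assert f5.Tz == pytest.approx(5 * f1.Tz, rel=1e-10)

    def test_superposition_of_ambient_and_motion(self, fluid, channel, op_near_wall_coarse):
        """Solutions superpose: (shear + translation) equals the sum of
        the separate solves."""
        sp = op_near_wall_coarse.sphere
        p_shear = make_problem(fluid, channel, sp)
        p_trans = make_problem(fluid, channel, sp, gammadot=0.0, kinematics=(1e-5, 0.0))
        p_both = make_problem(fluid, channel, sp, kinematics=(1e-5, 0.0))
        f_shear = force_torque(solve_flow(p_shear, operator=op_near_wall_coarse))
        f_trans = force_torque(solve_flow(p_trans, operator=op_near_wall_coarse))
        f_both = force_torque(solve_flow(p_both, operator=op_near_wall_coarse))
        assert f_both.Fx == pytest.approx(f_shear.Fx + f_trans.Fx, rel=1e-9)
        assert f_both.Tz == pytest.approx(f_shear.Tz + f_trans.Tz, rel=1e-9)

    def test_inertial_correction_estimate_small(self, fluid, channel, op_near_wall_coarse):
        """At WSS = 5 dyn/cm^2 the convective-term correction estimate is
        below 2% (creeping-flow regime)."""
        sp = op_near_wall_coarse.sphere
        cond = FlowConditions.from_dyn_cm2(5.0, ProfileKind.PARABOLIC)
        prob = FlowProblem(fluid=fluid, channel=channel, conditions=cond,
                           sphere=sp, include_convective_term=True)
        sol = solve_flow(prob, operator=op_near_wall_coarse)
        assert sol.metadata["inertial_relative_correction"] < 0.02


class TestConservationAndDomain:
    def test_mass_conservation(self, fluid, channel, op_near_wall_coarse):
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere)
        sol = solve_flow(prob, operator=op_near_wall_coarse)
        dom = build_reduced_domain(op_near_wall_coarse.sphere, channel, resolution="coarse")
        rep = check_mass_conservation(sol, domain=dom)
        assert rep.relative_imbalance < 1e-6
        assert rep.sphere_surface_flux < 1e-6
        assert rep.passed

    def test_sampled_divergence_small(self, fluid, channel, op_near_wall_coarse):
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere)
        sol = solve_flow(prob, operator=op_near_wall_coarse)
        dom = build_reduced_domain(op_near_wall_coarse.sphere, channel, resolution="coarse")
        rep = check_mass_conservation(sol, domain=dom)
        assert rep.max_divergence < 1e-4  # finite-difference floor

    def test_domain_doubling_changes_force_below_1pct(self, fluid, channel,
                                                      op_near_wall_coarse):
        """The inviscid-boundary residual of the reduced domain shifts
        the force by < 1%, and less for the doubled domain."""
        prob = make_problem(fluid, channel, op_near_wall_coarse.sphere)
        sol = solve_flow(prob, operator=op_near_wall_coarse)
        dom = build_reduced_domain(op_near_wall_coarse.sphere, channel, resolution="coarse")
        est = domain_sensitivity(sol, dom)
        est2 = domain_sensitivity(sol, dom, doubled=True)
        assert est["relative_force_change"] < 0.01
        assert est2["relative_force_change"] < est["relative_force_change"]
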