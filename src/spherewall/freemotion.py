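"""Force-free, torque-free (freely rolling/translating) sphere motion.

A neutrally buoyant sphere carried by the flow settles into a
quasi-steady state in which the net hydrodynamic force and torque both
vanish.  Only the downstream translation u and the spanwise rolling
rate omega are free (wall-normal migration and lateral drift are frozen
by the symmetry of the configuration and gravity is neglected), so the
state solves the 2x2 mobility problem

    [ R_Fu  R_Fw ] [ u     ]   [ F0 ]
    [ R_Tu  R_Tw ] [ omega ] = -[ T0 ],

where the resistance entries are the force/torque per unit translation
and unit rolling in quiescent fluid and (F0, T0) is the load on the
held-fixed sphere in the ambient profile.  Under Stokes linearity this
superposition is exact and needs three solves sharing one matrix
factorization.  A damped fixed-point iteration mimicking quasi-static
time stepping is provided as an alternative mode; it converges to the
same state and also accepts the perturbative inertial estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ReducedDomain
from .solver import (
    ConvectiveModeError,
    FlowProblem,
    WallStokesOperator,
    solve_flow,
)
from .tractions import force_torque

__all__ = [
    "ResistanceMatrix",
    "FreeMotionResult",
    "resistance_matrix",
    "solve_free_motion",
    "quasi_static_iterate",
]


@dataclass
class ResistanceMatrix:
    """2x2 resistance coupling (u, omega) -> (Fx, Tz) plus the ambient
    load on the held-fixed sphere.

    Signs follow the reporting convention (u downstream, omega forward
    rolling); the diagonal is negative (drag opposes motion) and the
    off-diagonal couplings agree up to discretization error by the
    Lorentz reciprocal theorem.
    """

    R: np.ndarray  # (2, 2): rows (Fx, Tz), cols (u, omega)
    ambient_load: np.ndarray  # (2,): (F0, T0) for the held-fixed sphere
    operator: WallStokesOperator = field(repr=False, default=None)  # type: ignore[assignment]

    def symmetry_defect(self) -> float:
        """Relative mismatch of the reciprocal couplings."""
        b, c = self.R[0, 1], self.R[1, 0]
        return float(abs(b - c) / max(abs(b), abs(c), 1e-300))

    def is_dissipative(self) -> bool:
        return bool(self.R[0, 0] < 0 and self.R[1, 1] < 0)


def _load(problem: FlowProblem, operator: WallStokesOperator):
    sol = solve_flow(problem, operator=operator)
    ft = force_torque(sol)
    return np.array([ft.Fx, ft.Tz]), sol


def resistance_matrix(
    problem: FlowProblem,
    domain: ReducedDomain | None = None,
    operator: WallStokesOperator | None = None,
) -> ResistanceMatrix:
    """Assemble the resistance matrix from three Stokes solves (held
    fixed in the ambient flow; unit translation; unit rolling) sharing
    one factorization.  Refuses the convective mode, where
    superposition is invalid (use :func:`quasi_static_iterate`)."""
    if problem.include_convective_term:
        raise ConvectiveModeError(
            "superposition requires the Stokes mode; use quasi_static_iterate"
        )
    if problem.sphere is None:
        raise ValueError("free motion needs a sphere")
    if operator is None:
        operator = WallStokesOperator(problem.sphere, resolution="medium")
    from dataclasses import replace

    quiet = replace(
        problem,
        conditions=type(problem.conditions)(wss=0.0, profile_kind=problem.conditions.profile_kind),
    )
    load0, _ = _load(replace(problem, kinematics=(0.0, 0.0)), operator)
    load_u, _ = _load(replace(quiet, kinematics=(1.0, 0.0)), operator)
    load_w, _ = _load(replace(quiet, kinematics=(0.0, 1.0)), operator)
    R = np.column_stack([load_u, load_w])
    return ResistanceMatrix(R=R, ambient_load=load0, operator=operator)


@dataclass
class FreeMotionResult:
    """Free-motion state: u (m/s), omega (rad/s, forward-rolling
    positive), residual force (N) and torque (N m) at the solution."""

    u: float
    omega: float
    residual_force: float
    residual_torque: float
    mode: str
    iterations: int = 0
    history: list = field(default_factory=list)

    @property
    def u_um_s(self) -> float:
        return self.u * 1e6


def solve_free_motion(
    problem: FlowProblem,
    domain: ReducedDomain | None = None,
    operator: WallStokesOperator | None = None,
    rm: ResistanceMatrix | None = None,
    residual_tol: float = 0.005,
) -> FreeMotionResult:
    """Mobility (superposition) solution of the free-motion condition,
    verified by one confirming solve at the computed (u, omega)."""
    from dataclasses import replace

    if rm is None:
        rm = resistance_matrix(problem, domain=domain, operator=operator)
        load0 = rm.ambient_load
    else:
        # a resistance matrix is purely geometric: recompute the ambient
        # load for this problem's profile and shear rate
        load0, _ = _load(replace(problem, kinematics=(0.0, 0.0)), rm.operator)
    if abs(np.linalg.det(rm.R)) < 1e-300:
        raise np.linalg.LinAlgError("singular resistance matrix")
    u, om = np.linalg.solve(rm.R, -load0)

    load, _ = _load(replace(problem, kinematics=(float(u), float(om))), rm.operator)
    scale = np.abs(load0)
    rel = np.abs(load) / np.maximum(scale, 1e-300)
    res = FreeMotionResult(
        u=float(u),
        omega=float(om),
        residual_force=float(load[0]),
        residual_torque=float(load[1]),
        mode="mobility",
    )
    if np.any(rel > residual_tol):
        res.mode = "mobility (residual above tolerance)"
    return res


def quasi_static_iterate(
    problem: FlowProblem,
    domain: ReducedDomain | None = None,
    operator: WallStokesOperator | None = None,
    initial: tuple[float, float] = (0.0, 0.0),
    damping: float = 0.7,
    residual_tol: float = 0.005,
    max_steps: int = 200,
) -> FreeMotionResult:
    """Damped fixed-point iteration on (u, omega) driven by the
    force/torque imbalance, mimicking quasi-static time stepping with a
    mesh updated to the current sphere kinematics.

    The update scales the imbalance by the unbounded-fluid drag
    coefficients (6 pi mu a, 8 pi mu a^3); the wall makes the true drag
    larger, so the effective relaxation factor is below one and the
    iteration contracts, typically settling within a few tens of steps.
    Divergence triggers step halving.
    """
    if problem.sphere is None:
        raise ValueError("free motion needs a sphere")
    if operator is None:
        operator = WallStokesOperator(problem.sphere, resolution="medium")
    from dataclasses import replace

    mu = problem.fluid.dynamic_viscosity
    a = problem.sphere.radius
    cF = 6.0 * np.pi * mu * a
    cT = 8.0 * np.pi * mu * a ** 3
    load0, _ = _load(replace(problem, kinematics=(0.0, 0.0)), operator)
    scale = np.maximum(np.abs(load0), 1e-300)

    u, om = float(initial[0]), float(initial[1])
    lam = float(damping)
    history: list[tuple[float, float, float, float]] = []
    prev_norm = np.inf
    for step in range(1, max_steps + 1):
        load, _ = _load(replace(problem, kinematics=(u, om)), operator)
        rel = np.abs(load) / scale
        history.append((u, om, float(load[0]), float(load[1])))
        if np.all(rel < residual_tol):
            return FreeMotionResult(
                u=u, omega=om, residual_force=float(load[0]),
                residual_torque=float(load[1]), mode="quasi-static",
                iterations=step, history=history,
            )
        norm = float(np.max(rel))
        if norm > 1.2 * prev_norm:
            lam *= 0.5  # step halving on divergence
            if lam < 1e-4:
                raise RuntimeError("quasi-static iteration diverged")
        prev_norm = norm
        u += lam * load[0] / cF
        om += lam * load[1] / cT
    raise RuntimeError(
        f"quasi-static iteration did not reach tolerance in {max_steps} steps"
    )
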