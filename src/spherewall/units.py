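"""Unit conventions, wall-shear conversions and inlet velocity profiles.

Everything inside the package is SI (m, s, Pa, N).  User-facing entry
points accept and report the units conventional in cell-rolling
hemodynamics: wall shear stress in dynes cm^-2, force in pN, torque in
pN um, velocity in um s^-1.  The only non-trivial conversion constant is

    1 dyn cm^-2 = 0.1 Pa.

Two inlet profiles are supported.  ``parabolic`` is the fully developed
(Poiseuille) channel profile written in terms of the wall shear stress
tau_w on the lower plate of a channel of height 2H,

    Vx(Y) = -(tau_w / (2 mu H)) * (Y^2 - H^2),   -H <= Y <= H,

with Y measured from the channel mid-plane.  ``linear`` is the uniform
shear (Couette) profile Vx = gammadot * (Y + H) assumed by the classical
Goldman wall-correction model; both profiles produce the same wall shear
stress and wall shear rate at the lower plate Y = -H.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "DYN_PER_CM2",
    "FluidProperties",
    "ChannelSpec",
    "ProfileKind",
    "FlowConditions",
    "wss_to_wall_shear_rate",
    "wall_shear_rate_to_wss",
    "inlet_velocity_profile",
    "inlet_profile_flux",
    "reynolds_number",
    "WATER_LIKE",
]

#: Pa per dyn cm^-2
DYN_PER_CM2 = 0.1


class InvalidFluidError(ValueError):
    """Raised for non-physical fluid parameters (e.g. mu <= 0)."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid parameters.

    Parameters
    ----------
    dynamic_viscosity:
        mu in Pa s (N s m^-2).
    density:
        rho in kg m^-3.
    """

    dynamic_viscosity: float
    density: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.dynamic_viscosity > 0):
            raise InvalidFluidError(
                f"dynamic viscosity must be positive, got {self.dynamic_viscosity}"
            )
        if not (self.density > 0):
            raise InvalidFluidError(f"density must be positive, got {self.density}")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho in m^2 s^-1."""
        return self.dynamic_viscosity / self.density


#: Buffer used in the perfusion experiments the solver emulates.
WATER_LIKE = FluidProperties(dynamic_viscosity=0.0009, density=1000.0)


@dataclass(frozen=True)
class ChannelSpec:
    """Parallel-plate channel geometry.

    ``half_height`` is H; the full channel height is 2H (default
    100 um).  Width and length describe the physical device and are
    carried for reporting; the flow model only needs H.
    """

    half_height: float = 50e-6
    full_width: float = 2e-3
    full_length: float = 14e-3

    def __post_init__(self) -> None:
        if not (self.half_height > 0):
            raise ValueError("channel half-height must be positive")

    @property
    def height(self) -> float:
        """Full channel height 2H in m."""
        return 2.0 * self.half_height


class ProfileKind(str, enum.Enum):
    LINEAR = "linear"
    PARABOLIC = "parabolic"


@dataclass(frozen=True)
class FlowConditions:
    """Imposed flow forcing: wall shear stress and profile shape.

    ``wss`` is stored in Pa; use :func:`FlowConditions.from_dyn_cm2`
    for the conventional CGS input.
    """

    wss: float
    profile_kind: ProfileKind = ProfileKind.PARABOLIC

    def __post_init__(self) -> None:
        if self.wss < 0:
            raise ValueError("wall shear stress must be >= 0")

    @classmethod
    def from_dyn_cm2(
        cls, wss_dyn_cm2: float, profile_kind: ProfileKind | str = ProfileKind.PARABOLIC
    ) -> "FlowConditions":
        return cls(wss=wss_dyn_cm2 * DYN_PER_CM2, profile_kind=ProfileKind(profile_kind))

    @property
    def wss_dyn_cm2(self) -> float:
        return self.wss / DYN_PER_CM2

    def wall_shear_rate(self, fluid: FluidProperties) -> float:
        """gammadot = WSS / mu in s^-1."""
        return wss_to_wall_shear_rate(self.wss, fluid)


def wss_to_wall_shear_rate(wss: float, fluid: FluidProperties) -> float:
    """Convert wall shear stress (Pa) to wall shear rate (s^-1).

    WSS = mu * dVx/dY at the lower wall, so gammadot = WSS / mu.
    """
    if wss < 0:
        raise ValueError("wall shear stress must be >= 0")
    if not isinstance(fluid, FluidProperties):
        raise InvalidFluidError("fluid must be a FluidProperties instance")
    return wss / fluid.dynamic_viscosity


def wall_shear_rate_to_wss(shear_rate: float, fluid: FluidProperties) -> float:
    """Inverse of :func:`wss_to_wall_shear_rate`; round-trips exactly."""
    if shear_rate < 0:
        raise ValueError("shear rate must be >= 0")
    return shear_rate * fluid.dynamic_viscosity


def inlet_velocity_profile(
    Y,
    cond: FlowConditions,
    fluid: FluidProperties,
    channel: ChannelSpec,
):
    """Streamwise velocity Vx(Y) of the undisturbed inlet flow in m s^-1.

    ``Y`` is measured from the channel mid-plane (wall at Y = -H) and may
    be a scalar or ndarray.  For the parabolic profile Y must lie inside
    the channel; the linear profile only requires Y >= -H (it is the
    unbounded-shear extension used by the Goldman model).
    """
    import numpy as np

    Y = np.asarray(Y, dtype=float)
    H = channel.half_height
    gammadot = cond.wall_shear_rate(fluid)
    if cond.profile_kind is ProfileKind.PARABOLIC:
        if np.any(Y < -H - 1e-12 * H) or np.any(Y > H + 1e-12 * H):
            raise ValueError("Y outside channel [-H, H] for parabolic profile")
        v = -(cond.wss / (2.0 * fluid.dynamic_viscosity * H)) * (Y * Y - H * H)
    else:
        if np.any(Y < -H - 1e-12 * H):
            raise ValueError("Y below the lower wall for linear profile")
        v = gammadot * (Y + H)
    return v if v.ndim else float(v)


def inlet_profile_flux(
    cond: FlowConditions, fluid: FluidProperties, channel: ChannelSpec
) -> float:
    """Volumetric flux per unit channel width, integral of Vx over [-H, H].

    For the parabolic profile this equals the Poiseuille value
    (2/3) * Vmax * 2H with Vmax = WSS*H/(2 mu).
    """
    H = channel.half_height
    gammadot = cond.wall_shear_rate(fluid)
    if cond.profile_kind is ProfileKind.PARABOLIC:
        vmax = cond.wss * H / (2.0 * fluid.dynamic_viscosity)
        return (2.0 / 3.0) * vmax * channel.height
    return 0.5 * gammadot * channel.height ** 2


def reynolds_number(
    cond: FlowConditions, fluid: FluidProperties, sphere_diameter: float
) -> float:
    """Particle shear Reynolds number Re = gammadot * d^2 / nu.

    The near-wall flow has no imposed velocity scale independent of the
    shear rate, so the particle Reynolds number is built from the wall
    shear rate and the sphere diameter.  For the whole wall-shear-stress
    range used in cell-rolling assays (0.1-5 dyn cm^-2, d ~ 10 um) this
    is well below unity, which is what licenses the Stokes (creeping
    flow) default of the solver.
    """
    if sphere_diameter < 0:
        raise ValueError("sphere diameter must be >= 0")
    gammadot = cond.wall_shear_rate(fluid)
    return gammadot * sphere_diameter ** 2 / fluid.kinematic_viscosity
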