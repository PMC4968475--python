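"""Goldman-model reference: wall-correction factors for a sphere in
linear shear near a single plane wall.

The classical treatment of a sphere of radius a at gap h from a wall in
unbounded simple shear (Couette flow, shear rate gammadot) reduces, at
zero Reynolds number, to dimensionless wall-correction factors that
depend only on eps = h/a:

* stationary sphere:  Fx = 6 pi mu a V_c F*(eps),  V_c = gammadot (a + h)
                      Tz = 4 pi mu a^3 gammadot T*(eps)
* free motion:        u  = gammadot (a + h) U*(eps)
                      omega = gammadot W*(eps)

As eps -> infinity, F*, T* -> 1, U* -> 1 and W* -> 1/2 (free sphere in
unbounded shear); towards contact F* and T* plateau near 1.70 and 0.94
while U* and W* fall off logarithmically slowly.

The bundled coefficient table was computed with this package's own
wall-bounded solver in linear-profile mode at fine resolution with
Richardson extrapolation over the two finest grids (the original
bipolar-coordinate series is not re-derived here); alternatively any
user-supplied table with the same columns can be loaded, or the factors
can be recomputed live.  Interpolation is monotone cubic in log(eps).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .geometry import SphereSpec
from .units import ChannelSpec, FluidProperties, FlowConditions, ProfileKind

__all__ = [
    "GoldmanResult",
    "WallFactorTable",
    "load_factor_table",
    "goldman_stationary",
    "goldman_free_motion",
]

_TABLE_RESOURCE = "goldman_wall_factors.txt"
_COLUMNS = ("eps", "F_star", "T_star", "U_star", "W_star")


class ContactSingularityError(ValueError):
    """h <= 0: the resistance diverges at contact."""


@dataclass
class GoldmanResult:
    """Reference values at one geometry, with the factors used."""

    Fx: float  # N
    Tz: float  # N m, forward-rolling axis
    u: float  # m/s
    omega: float  # rad/s
    eps: float
    factors: dict
    provenance: str

    @property
    def Fx_pN(self) -> float:
        return self.Fx * 1e12

    @property
    def Tz_pN_um(self) -> float:
        return self.Tz * 1e18

    @property
    def u_um_s(self) -> float:
        return self.u * 1e6


class WallFactorTable:
    """Correction-factor table over eps = h/a with monotone-cubic
    interpolation in log(eps); clamps to the tabulated end values
    outside the grid (both ends plateau)."""

    def __init__(self, eps: np.ndarray, data: dict[str, np.ndarray], provenance: str):
        order = np.argsort(eps)
        self.eps = np.asarray(eps, dtype=float)[order]
        self.provenance = provenance
        self._interp = {
            k: PchipInterpolator(np.log(self.eps), np.asarray(v, dtype=float)[order])
            for k, v in data.items()
        }
        self._data = {k: np.asarray(v, dtype=float)[order] for k, v in data.items()}

    def __call__(self, eps: float) -> dict[str, float]:
        if eps <= 0:
            raise ContactSingularityError("eps = h/a must be positive")
        x = np.clip(np.log(eps), np.log(self.eps[0]), np.log(self.eps[-1]))
        return {k: float(f(x)) for k, f in self._interp.items()}

    @classmethod
    def from_file(cls, path: str | Path) -> "WallFactorTable":
        path = Path(path)
        prov = []
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                prov.append(line.lstrip("# "))
        arr = np.loadtxt(path)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != len(_COLUMNS):
            raise ValueError(f"expected columns {_COLUMNS}")
        data = {k: arr[:, i] for i, k in enumerate(_COLUMNS) if k != "eps"}
        return cls(arr[:, 0], data, provenance="\n".join(prov) or str(path))


_cached_table: WallFactorTable | None = None


def load_factor_table(path: str | Path | None = None) -> WallFactorTable:
    """Load the bundled (or a user-supplied) coefficient table."""
    global _cached_table
    if path is not None:
        return WallFactorTable.from_file(path)
    if _cached_table is None:
        res = importlib.resources.files("spherewall.data") / _TABLE_RESOURCE
        with importlib.resources.as_file(res) as p:
            _cached_table = WallFactorTable.from_file(p)
    return _cached_table


def _factors(eps: float, source: str, resolution: str) -> tuple[dict, str]:
    if source == "tabulated":
        tab = load_factor_table()
        return tab(eps), "tabulated: " + tab.provenance.splitlines()[0]
    if source == "computed":
        return compute_factors(eps, resolution=resolution), f"computed ({resolution})"
    raise ValueError("source must be 'tabulated' or 'computed'")


def goldman_stationary(
    gammadot: float,
    a: float,
    h: float,
    mu: float,
    source: str = "tabulated",
    resolution: str = "medium",
) -> GoldmanResult:
    """Force and torque on a sphere held fixed in near-wall shear.

    Parameters are the shear rate (s^-1), sphere radius a (m), gap h
    (m) and viscosity mu (Pa s); results in SI with pN / pN um
    accessors.
    """
    if h <= 0:
        raise ContactSingularityError("gap h must be positive")
    eps = h / a
    fac, prov = _factors(eps, source, resolution)
    Vc = gammadot * (a + h)
    Fx = 6.0 * np.pi * mu * a * Vc * fac["F_star"]
    Tz = 4.0 * np.pi * mu * a ** 3 * gammadot * fac["T_star"]
    u = Vc * fac["U_star"]
    om = gammadot * fac["W_star"]
    return GoldmanResult(Fx=Fx, Tz=Tz, u=u, omega=om, eps=eps, factors=fac, provenance=prov)


def goldman_free_motion(
    gammadot: float,
    a: float,
    h: float,
    mu: float,
    source: str = "tabulated",
    resolution: str = "medium",
) -> GoldmanResult:
    """Translational and angular velocity of the force- and torque-free
    sphere in near-wall shear (same factor source as the stationary
    case)."""
    return goldman_stationary(gammadot, a, h, mu, source=source, resolution=resolution)


def compute_factors(eps: float, resolution: str = "medium") -> dict[str, float]:
    """Compute the wall-correction factors live with the linear-mode
    wall-bounded solver (viscosity and shear rate cancel out of the
    dimensionless factors)."""
    from .freemotion import resistance_matrix, solve_free_motion
    from .solver import FlowProblem, WallStokesOperator, solve_flow
    from .tractions import force_torque

    a = 5e-6  # factors depend on eps only; any radius works
    sphere = SphereSpec(diameter=2 * a, gap=eps * a)
    mu, gammadot = 1e-3, 1.0
    fluid = FluidProperties(mu)
    channel = ChannelSpec(half_height=1.0)  # immaterial in linear mode
    cond = FlowConditions(wss=mu * gammadot, profile_kind=ProfileKind.LINEAR)
    prob = FlowProblem(fluid, channel, cond, sphere)
    op = WallStokesOperator(sphere, resolution=resolution)
    ft = force_torque(solve_flow(prob, operator=op))
    rm = resistance_matrix(prob, operator=op)
    free = solve_free_motion(prob, rm=rm)
    Vc = gammadot * (a + sphere.gap)
    return dict(
        F_star=ft.Fx / (6.0 * np.pi * mu * a * Vc),
        T_star=ft.Tz / (4.0 * np.pi * mu * a ** 3 * gammadot),
        U_star=free.u / Vc,
        W_star=free.omega / gammadot,
    )
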