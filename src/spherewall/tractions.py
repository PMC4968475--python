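"""Surface tractions and their force/torque resultants.

The hydrodynamic load on the sphere is the surface integral of the
traction t = sigma . n, split in the conventional way into a pressure
part and a viscous part:

    F = sum_i ( -P_i n_i + tau_i ) ds_i
    T = sum_i   r_i x ( tau_i ds_i )

over the N facets of the surface mesh.  Only the viscous part enters
the torque: on an exact sphere every facet normal passes through the
centre, so the pressure contribution to the moment vanishes
identically (the discrete value is checked as an invariant).

For the single-layer solver the physical traction equals minus the
solved density up to a uniform-pressure gauge; on a rigid no-slip
sphere the normal viscous stress vanishes pointwise (continuity plus
the rigidity of the surface velocity), so the pressure is read off the
normal traction component and the viscous stress vector is its
tangential remainder.

Sign conventions: Fx positive downstream; the reported torque Tz is
about the forward-rolling axis (positive when the load spins the
sphere the way a sphere rolls downstream along the wall).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import SurfaceMesh
from .solver import ROLL_AXIS, FlowSolution

__all__ = [
    "TractionField",
    "ForceTorque",
    "surface_tractions",
    "integrate_force_torque",
    "force_torque",
    "write_results",
]

PN = 1e12  # N -> pN
PN_UM = 1e18  # N m -> pN um


@dataclass
class TractionField:
    """Per-facet pressure (Pa, gauge-relative) and viscous traction
    vector tau . n (Pa) on a closed sphere mesh."""

    pressure: np.ndarray  # (N,)
    viscous: np.ndarray  # (N, 3)
    mesh: SurfaceMesh

    def total(self) -> np.ndarray:
        """Full traction vectors -P n + tau . n."""
        return -self.pressure[:, None] * self.mesh.normals + self.viscous


@dataclass
class ForceTorque:
    """Force (N) and torque (N m) resultants; Fx/Tz are the reported
    scalars, the full vectors are retained for symmetry diagnostics."""

    force: np.ndarray  # (3,) right-handed components
    torque: np.ndarray  # (3,) right-handed components about sphere centre

    @property
    def Fx(self) -> float:
        return float(self.force[0])

    @property
    def Tz(self) -> float:
        """Torque about the forward-rolling axis."""
        return float(self.torque @ ROLL_AXIS)

    @property
    def Fx_pN(self) -> float:
        return self.Fx * PN

    @property
    def Tz_pN_um(self) -> float:
        return self.Tz * PN_UM

    def symmetry_defect(self) -> float:
        """Largest off-plane component relative to the in-plane load;
        small for the spanwise-symmetric configurations studied here."""
        f_ref = max(abs(self.Fx), 1e-300)
        t_ref = max(abs(self.Tz), 1e-300)
        return max(
            abs(self.force[1]) / f_ref if abs(self.force[1]) < np.inf else 0.0,
            abs(self.force[2]) / f_ref,
            abs(self.torque[0]) / t_ref,
            abs(self.torque[1]) / t_ref,
        )


def surface_tractions(sol: FlowSolution, mesh: SurfaceMesh | None = None) -> TractionField:
    """Extract the traction field of a converged solution on its own
    surface quadrature mesh."""
    if sol.operator is None:
        raise ValueError("solution has no sphere surface")
    own = sol.operator.as_surface_mesh()
    if mesh is not None and mesh.n_facets != own.n_facets:
        raise ValueError("mesh inconsistent with the solved geometry")
    mesh = own
    t_total = -sol.density  # up to a uniform-pressure gauge
    # gauge: zero area-weighted mean normal traction (ambient reference)
    tn = np.einsum("ij,ij->i", t_total, mesh.normals)
    gauge = np.sum(tn * mesh.areas) / mesh.total_area
    tn = tn - gauge
    pressure = -tn
    viscous = (t_total - gauge * mesh.normals) + pressure[:, None] * mesh.normals
    return TractionField(pressure=pressure, viscous=viscous, mesh=mesh)


def integrate_force_torque(tr: TractionField, mesh: SurfaceMesh) -> ForceTorque:
    """Discrete facet sums of the traction resultants about the sphere
    centre; requires a closed mesh."""
    if mesh.closed_surface_defect() > 1e-3:
        raise ValueError("open surface mesh: closed-surface identity violated")
    ds = mesh.areas[:, None]
    force = (-tr.pressure[:, None] * mesh.normals * ds + tr.viscous * ds).sum(axis=0)
    torque = np.cross(mesh.centroids, tr.viscous * ds).sum(axis=0)
    return ForceTorque(force=force, torque=torque)


def force_torque(sol: FlowSolution) -> ForceTorque:
    """Convenience wrapper: traction extraction + integration."""
    tr = surface_tractions(sol)
    return integrate_force_torque(tr, tr.mesh)


def write_results(rows: list[dict], path: str | Path, fmt: str | None = None) -> Path:
    """Write case results as CSV (via pandas) or JSON.

    Expected per-row keys follow the reporting schema: case id, wss
    (dyn cm^-2), profile, h_um, d_um, Fx_pN, Tz_pNum, and optionally
    u_um_s, omega_rad_s, resolution, residuals, mode.
    """
    import pandas as pd

    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "csv")
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2, default=float) + "\n")
    else:
        pd.DataFrame(rows).to_csv(path, index=False)
    return path
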