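"""Named case presets for every printed comparison case.

Each preset is a flat dict in report units (dyn cm^-2, um) that
``build_problem`` converts to a :class:`~spherewall.solver.FlowProblem`.
"""

from __future__ import annotations

from .geometry import SphereSpec
from .solver import FlowProblem
from .units import ChannelSpec, FlowConditions, FluidProperties, ProfileKind

__all__ = ["PRESETS", "build_problem"]

PRESETS: dict[str, dict] = {
    # stationary-sphere comparison triple at WSS = 0.1 dyn cm^-2
    "table1_caseA": dict(
        mu_Pa_s=0.0009, rho=1000.0, height_um=100.0, wss_dyn_cm2=0.1,
        profile="parabolic", d_um=10.0, h_um=0.069, mode="stationary",
    ),
    "table1_caseB": dict(
        mu_Pa_s=0.0009, rho=1000.0, height_um=100.0, wss_dyn_cm2=0.1,
        profile="linear", d_um=10.0, h_um=0.069, mode="stationary",
    ),
    "table1_caseC": dict(
        mu_Pa_s=0.0009, rho=1000.0, height_um=100.0, wss_dyn_cm2=0.1,
        profile="linear", d_um=10.0, h_um=0.069, mode="goldman",
    ),
    # lymphoid-cell comparison (mu = 0.001, gammadot = 1.32 /s, d = 12 um)
    "tissot": dict(
        mu_Pa_s=0.001, rho=1000.0, height_um=100.0, shear_rate_per_s=1.32,
        profile="parabolic", d_um=12.0, h_um=1.4, mode="free",
    ),
    "tissot_goldman": dict(
        mu_Pa_s=0.001, rho=1000.0, height_um=100.0, shear_rate_per_s=1.32,
        profile="linear", d_um=12.0, h_um=1.4, mode="goldman_free",
    ),
    # free-motion WSS sweep grid
    "fig6_wss_grid": dict(
        mu_Pa_s=0.0009, rho=1000.0, height_um=100.0,
        wss_dyn_cm2=[0.1, 0.25, 0.5, 1.0, 2.5, 5.0],
        profile="parabolic", d_um=10.0, h_um=0.069, mode="free",
    ),
}


def build_problem(cfg: dict, wss_dyn_cm2: float | None = None) -> FlowProblem:
    """Build a FlowProblem from a flat preset/config dict."""
    fluid = FluidProperties(cfg["mu_Pa_s"], cfg.get("rho", 1000.0))
    channel = ChannelSpec(half_height=0.5 * cfg.get("height_um", 100.0) * 1e-6)
    if wss_dyn_cm2 is None:
        if "wss_dyn_cm2" in cfg:
            wss_dyn_cm2 = cfg["wss_dyn_cm2"]
            if isinstance(wss_dyn_cm2, (list, tuple)):
                raise ValueError("pass a single WSS value (sweep grids use run_sweep)")
        else:
            wss_dyn_cm2 = cfg["shear_rate_per_s"] * cfg["mu_Pa_s"] / 0.1
    cond = FlowConditions.from_dyn_cm2(wss_dyn_cm2, ProfileKind(cfg.get("profile", "parabolic")))
    sphere = SphereSpec(diameter=cfg["d_um"] * 1e-6, gap=cfg["h_um"] * 1e-6)
    return FlowProblem(fluid=fluid, channel=channel, conditions=cond, sphere=sphere)
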