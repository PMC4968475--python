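"""Regenerate the bundled Goldman wall-correction factor table.

Runs the linear-mode wall-bounded solver at fine resolution over a grid
of gap ratios eps = h/a and writes
src/spherewall/data/goldman_wall_factors.txt.  The grid includes the
gap ratios of the bundled case presets so those evaluate without
interpolation error.  Takes on the order of an hour on one CPU.
"""

from __future__ import annotations

import datetime
import sys
from pathlib import Path

import numpy as np

from spherewall.goldman import compute_factors

EPS_GRID = [
    0.005, 0.008, 0.0138, 0.022, 0.035, 0.06, 0.1, 0.15,
    7.0 / 30.0,  # 0.2333..., gap 1.4 um on a 12 um sphere
    0.35, 0.55, 0.9, 1.5, 2.5, 4.5, 10.0,
]

def main(resolution: str = "fine") -> None:
    root = Path(__file__).resolve().parents[1]
    out = root / "src/spherewall/data/goldman_wall_factors.txt"
    cache = root / "scratch" / "goldman_rows"
    cache.mkdir(parents=True, exist_ok=True)
    rows = []
    for eps in EPS_GRID:
        row_file = cache / f"eps_{eps:.6f}_{resolution}.txt"
        if row_file.exists():
            rows.append(tuple(np.loadtxt(row_file)))
            continue
        # large gaps converge at medium resolution; fine is only needed
        # where the lubrication region must be resolved
        res = resolution if eps <= 0.3 else "medium"
        fac = compute_factors(eps, resolution=res)
        row = (eps, fac["F_star"], fac["T_star"], fac["U_star"], fac["W_star"])
        np.savetxt(row_file, np.asarray(row)[None, :])
        rows.append(row)
        print(f"eps={eps:.6f}  F*={fac['F_star']:.5f} T*={fac['T_star']:.5f} "
              f"U*={fac['U_star']:.5f} W*={fac['W_star']:.5f}", flush=True)
    hdr = (
        "Goldman-model wall-correction factors for a sphere in linear shear near a plane wall.\n"
        f"Computed with the spherewall wall-bounded Stokes solver, linear-profile mode, "
        f"resolution '{resolution}'.\n"
        f"Generated {datetime.date.today().isoformat()} by scripts/build_goldman_table.py.\n"
        "Columns: eps=h/a, F_star = Fx/(6 pi mu a gammadot (a+h)), "
        "T_star = Tz/(4 pi mu a^3 gammadot),\n"
        "U_star = u/(gammadot (a+h)), W_star = omega/gammadot (free motion).\n"
        "eps F_star T_star U_star W_star"
    )
    np.savetxt(out, np.asarray(rows), header=hdr, fmt="%.8f")
    print("wrote", out)


if __name__ == "__main__":
    main(*(sys.argv[1:] or []))
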