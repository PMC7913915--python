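"""Regenerate the packaged sucrose freezing-point-depression table.

The table maps g sucrose per 100 g water to the equilibrium freezing-point
depression of the solution.  Water activity comes from the Norrish equation
for sucrose (K = 6.47); the freezing temperature solves the ice-solution
equilibrium with a temperature-dependent latent heat of fusion.  The dilute
limit reproduces the cryoscopic constant of water (1.86 degC/molal).

Usage: python scripts/make_sucrose_table.py [out.csv]
"""

import sys

import numpy as np
from scipy.optimize import brentq

MW_WATER = 18.015
MW_SUCROSE = 342.30
K_NORRISH = 6.47  # sucrose
DH_FUS0 = 6009.5  # J/mol at 273.15 K
DCP_FUS = 38.0  # J/mol/K, Cp(liquid) - Cp(ice)
T0 = 273.15
R = 8.314462


def water_activity(g_per_100g_water: float) -> float:
    ns = g_per_100g_water / MW_SUCROSE
    nw = 100.0 / MW_WATER
    xs = ns / (ns + nw)
    return float(np.exp(np.log(1.0 - xs) - K_NORRISH * xs**2))


def ln_aw_at_freezing(tf_kelvin: float) -> float:
    return -(1.0 / R) * (
        (DH_FUS0 - DCP_FUS * T0) * (1.0 / tf_kelvin - 1.0 / T0)
        + DCP_FUS * np.log(T0 / tf_kelvin)
    )


def fpd(g_per_100g_water: float) -> float:
    if g_per_100g_water == 0:
        return 0.0
    target = np.log(water_activity(g_per_100g_water))
    tf = brentq(lambda T: ln_aw_at_freezing(T) - target, 150.0, T0, xtol=1e-10)
    return T0 - tf


def main(out_path: str) -> None:
    grid = np.arange(0.0, 201.0, 5.0)
    lines = [
        "# sucrose freezing point depression, v1",
        "# g sucrose per 100 g water, FPD degC",
        "se_g_per_100g_water,fpd_c",
    ]
    lines += [f"{g:.1f},{fpd(g):.5f}" for g in grid]
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    print(f"wrote {out_path} ({grid.size} rows)")


if __name__ == "__main__":
    main(sys.argv[1] if len(sys.argv) > 1 else "src/icekin/data/sucrose_fpd_v1.csv")
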