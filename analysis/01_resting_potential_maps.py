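#!/usr/bin/env python
"""Resting-potential conductance maps of the sodium-zeroed model.

What this computes
------------------
1. The four reference operating points: at g_h = 0.5 mS/cm^2, varying
   g_Kir from 0 to 1 mS/cm^2 moves the resting potential from about -52
   to -63 mV, while varying g_h over the same span at g_Kir = 0.5 moves
   it only from about -58.5 to -55.6 mV - the Kir background, not the
   HCN conductance, sets the resting potential.
2. 2-D maps of the resting potential over (g_Kir, g_h), (g_h, g_leak)
   and (g_leak, g_Kir), each over [0, 2x baseline], with the
   quiet/active firing boundary from the full spiking model overlaid.
   The boundary tracks g_Kir and g_leak and is nearly vertical in g_h.

Outputs (results/): rmp_endpoints.csv, rmp_map_<axes>.csv and
boundary_<axes>.csv for each parameter plane.
"""

import pathlib

import numpy as np
import pandas as pd

from fusiform import workflows
from fusiform.parameters import ModelParameters, GH_MAP
from fusiform.scans import scan_2d, extract_boundary

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
N_GRID = 21  # per axis; the maps are smooth and well resolved at this size


def run_map(base, axis_x, axis_y, tag):
    grid = scan_2d(base, axis_x, axis_y, "rmp")
    grid.to_csv(OUT / f"rmp_map_{tag}.csv")
    boundary = extract_boundary(grid)
    pd.DataFrame(boundary["points"],
                 columns=[grid.x_name, grid.y_name]).to_csv(
        OUT / f"boundary_{tag}.csv", index=False)
    print(f"  {tag}: RMP spans {np.nanmin(grid.values):.1f} to "
          f"{np.nanmax(grid.values):.1f} mV; "
          f"{len(boundary['points'])} boundary points")
    return grid


def main():
    print("Reference operating points (sodium conductances zeroed):")
    table = workflows.rmp_endpoints()
    table.to_csv(OUT / "rmp_endpoints.csv", index=False)
    for _, r in table.iterrows():
        print(f"  g_h={r.g_h:.1f}, g_Kir={r.g_Kir:.1f} mS/cm^2 -> "
              f"RMP {r.rmp_mV:.2f} mV")
    d_kir = abs(table.rmp_mV.iloc[1] - table.rmp_mV.iloc[0])
    d_gh = abs(table.rmp_mV.iloc[3] - table.rmp_mV.iloc[2])
    print(f"  same-span sensitivity: {d_kir:.1f} mV for g_Kir vs "
          f"{d_gh:.1f} mV for g_h "
          f"({d_kir / d_gh:.1f}x stronger Kir control of RMP)\n")

    base = ModelParameters(g_h=GH_MAP)
    print(f"Conductance-space maps ({N_GRID}x{N_GRID}):")
    gh_ax = np.linspace(0.0, 2 * GH_MAP, N_GRID)
    gkir_ax = np.linspace(0.0, 2.0, N_GRID)        # 2x the quiet preset
    gleak_ax = np.linspace(0.0, 0.30, N_GRID)
    run_map(base, ("g_Kir", gkir_ax), ("g_h", gh_ax), "gkir_gh")
    run_map(base.replace(g_Kir=0.5), ("g_h", gh_ax), ("g_leak", gleak_ax),
            "gh_gleak")
    run_map(base, ("g_leak", gleak_ax), ("g_Kir", gkir_ax), "gleak_gkir")

    print("\nLeak-reversal map (g_leak x E_leak) at both Kir presets:")
    from fusiform.scans import scan_leak_reversal
    eleak_ax = np.linspace(-80.0, -35.0, N_GRID)
    for g_kir, tag in ((0.5, "active"), (1.0, "quiet")):
        grid = scan_leak_reversal(base, gleak_ax, eleak_ax, g_Kir=g_kir)
        grid.to_csv(OUT / f"rmp_map_gleak_eleak_{tag}.csv")
        hyper = grid.values[eleak_ax <= -65.0, :]
        print(f"  {tag} (g_Kir={g_kir}): with E_leak <= -65 mV the RMP "
              f"varies only {np.nanmax(np.ptp(hyper, axis=1)):.2f} mV "
              f"across the whole g_leak axis")


if __name__ == "__main__":
    main()
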