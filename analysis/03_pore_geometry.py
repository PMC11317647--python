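#!/usr/bin/env python
"""Pore-radius profiles and filter-geometry distributions on toy systems.

Profiles three analytically known toy pores (constant, stepped, hourglass)
with the maximal-inscribed-sphere algorithm and tabulates recovered vs true
radii; then builds a synthetic two-state distance series mimicking a
selectivity filter flipping between closed (~4 Å) and dilated (~12 Å)
intersubunit separations and characterises its bimodal density.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from permkit import build_toy_pore, pair_distance_distribution, radius_profile

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

profiles = {
    "constant": lambda z: 3.5,
    "step": lambda z: 4.0 if z < 0 else 1.0,
    "hourglass": lambda z: 1.0 + 0.06 * z * z,
}

frames = []
for name, fn in profiles.items():
    traj, truth = build_toy_pore(fn, z_range=(-8.0, 8.0))
    off = truth["z_offset"]
    z, r, _ = radius_profile(
        traj.frames[0], np.arange(traj.n_atoms), traj.topology.elements,
        truth["axis_xy"], (-6.0 + off, 6.0 + off), z_step=0.5,
        vdw_table=truth["vdw_table"], seed=0)
    true = truth["analytic_radius"](z - off)
    frames.append(pd.DataFrame({
        "pore": name, "z_A": z - off, "computed_A": r, "analytic_A": true}))
    print(f"{name:10s}: max |error| = {np.max(np.abs(r - true)):.4f} Å, "
          f"constriction {r.min():.2f} Å at z = {(z - off)[np.argmin(r)]:+.1f} Å")

pd.concat(frames).to_csv(OUT / "pore_radius_profiles.csv", index=False)

# two-state filter-separation series: equal occupancy at 4 and 12 Å
rng = np.random.default_rng(7)
series = np.concatenate([
    rng.normal(4.0, 0.25, 2000), rng.normal(12.0, 0.4, 2000)])
dist = pair_distance_distribution(series, bins=60, range=(0.0, 16.0))
modes = np.sort(dist["modes"])
print(f"two-state separation series: bimodal={dist['bimodal']}, "
      f"modes at {modes[0]:.1f} and {modes[-1]:.1f} Å")
pd.DataFrame({"distance_A": dist["centers"], "density": dist["density"]}).to_csv(
    OUT / "sf_separation_density.csv", index=False)
print(f"wrote profiles and densities to {OUT}/")
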