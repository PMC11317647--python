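#!/usr/bin/env python
"""Time-averaged cation density map of a drift trajectory.

Bins a permeation-rich synthetic run into a 3D number-density grid, checks
count conservation, verifies the high-density column sits on the pore axis,
and writes an OpenDX file loadable in standard molecular viewers.
"""

from pathlib import Path

import numpy as np

from permkit import DriftSpec, density_map, generate_drift_trajectory, write_dx

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

spec = DriftSpec(
    n_ions=12, n_waters=0, n_frames=400, dt=0.1, box=(40.0, 40.0, 80.0),
    drift_velocity=30.0, diffusion_coefficient=10.0, seed=2024,
)
traj, _ = generate_drift_trajectory(spec)
grid = density_map(traj, species="cation", spacing=2.0)

total = grid.counts.sum() + grid.overflow
assert total == spec.n_ions * spec.n_frames, "count conservation violated"

nx, ny, _ = grid.counts.shape
col = grid.counts[nx // 2 - 2: nx // 2 + 2, ny // 2 - 2: ny // 2 + 2, :].sum()
print(f"{int(grid.counts.sum())} in-bounds counts over {grid.n_frames} frames "
      f"({grid.overflow} overflow); pore-column share "
      f"{col / grid.counts.sum():.1%} of all occupancy in "
      f"{16 * 40 * 4 / (40 * 40 * 80):.1%} of the box volume")

write_dx(grid, OUT / "na_density.dx")
print(f"wrote {OUT / 'na_density.dx'} (peak density "
      f"{grid.density.max():.3g} ions/Å³)")
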