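#!/usr/bin/env python
"""Umbrella sampling + WHAM + bootstrap on an analytic free-energy surface.

Draws biased samples from a double-well with an 8 kcal/mol central barrier
(the energy scale of a closed selectivity filter) over 58 windows at 1 Å
spacing spanning ξ ∈ [−35, +22] Å, reconstructs the PMF with WHAM, attaches
100-replicate bootstrap error bars, and reports the barrier-recovery error.
Also assembles a per-window observable (a synthetic hydration count dipping
at the barrier) into a coordination-vs-ξ profile.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from permkit import (
    PMFSpec,
    bootstrap_errors,
    observable_vs_xi,
    sample_umbrella_windows,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 1
dw = PMFSpec(form="double-well", domain=(-35.0, 22.0),
             params={"a": 8.0, "b": 10.0, "center": -6.5})
centers = np.arange(-35.0, 22.01, 1.0)[:58]
windows = sample_umbrella_windows(dw, centers, k=2.39, n_samples=5000,
                                  seed=SEED)
prof = bootstrap_errors(windows, n_boot=100, seed=SEED)

between = (prof.xi > -16.5) & (prof.xi < 3.5)
barrier = float(np.nanmax(prof.W[between]))
print(f"58 windows x 5000 samples, k = 2.39 kcal/mol/Å² (1000 kJ/mol/nm²)")
print(f"recovered barrier {barrier:.2f} kcal/mol (true 8.00, "
      f"error {abs(barrier - 8.0):.2f}); median bootstrap SD "
      f"{float(np.nanmedian(prof.error)):.3f} kcal/mol")

prof.to_frame().to_csv(OUT / "pmf_double_well.csv", index=False)

# synthetic hydration observable: full shell (6) in bulk, dehydrated (2) at
# the barrier region, assembled per window at its centre
obs = [np.full(w.samples.size, 6.0 - 4.0 * np.exp(-((w.center + 6.5) / 4.0) ** 2))
       for w in windows]
xi, coord = observable_vs_xi(windows, obs, mode="per-window")
pd.DataFrame({"xi_A": xi, "water_coordination": coord}).to_csv(
    OUT / "coordination_vs_xi.csv", index=False)
print(f"coordination profile dips to {coord.min():.1f} at "
      f"ξ = {xi[np.argmin(coord)]:+.1f} Å (barrier at −6.5 Å)")
print(f"wrote PMF and coordination profiles to {OUT}/")
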