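# Methods

This note documents the models, conventions and numerical choices behind
permkit, and what the synthetic validation surface does and does not show.

## Units and geometry conventions

One internal convention throughout: lengths in Å, times in ns, voltages in
mV, charge in units of e, conductance in pS, energies in kcal/mol,
temperature in K.  Quantities commonly supplied in other MD units are
converted at ingest: force constants in kJ mol⁻¹ nm⁻² (×0.2390/100 →
kcal mol⁻¹ Å⁻²), times in ps (÷1000).  kBT at the default 310 K is
0.6160 kcal/mol (CODATA k_B).

Boxes are orthorhombic only; coordinates are treated as wrapped into the
primary box, and every distance is minimum-image.  Analyses that need
path continuity (event detection, the pore centre's own drift) unwrap the
relevant 1D coordinate internally.  Triclinic cells are out of scope.

## Permeation counting

The pore is a cylinder (default radius 6 Å) around a straight axis
(default +z) centred per frame on the unweighted centre of the
`center_selection` atoms (the geometric centre and the centre of mass are
interchangeable for the compact heavy-atom groups this anchors; with no
selection, the box centre).  Two planes relative to that centre — the
selectivity filter `z_sf` and the cytosolic gate `z_gate` — bound the pore
region, with `luminal_side` fixing which side is the lumen.

A forward event requires: luminal bulk → (between the planes, radially
inside the cylinder on every frame) → cytosolic bulk.  Design choices:

* **Hysteresis.** "Bulk" starts a margin (default 2 Å) beyond each plane,
  so an ion sitting on a plane cannot chatter events.
* **Strict cylinder containment** is the default reading of "only atoms in
  the cylinder are counted": an ion that exits radially mid-pore has its
  traversal invalidated and must revisit a bulk region before it can count
  again.  `strict_cylinder=False` instead only requires containment on the
  ion's last in-pore frame, for sensitivity analysis.
* Reverse traversals are recorded with direction −1 but excluded from the
  conductance count, which is directional by definition.
* A direct bulk→bulk transition with no in-pore frame (e.g. wrapping
  through the periodic boundary outside the channel) is never an event.

The implementation is checked two ways: planted, zero-diffusion crossings
must be recovered exactly for all planted counts 0–20, and on diffusive
trajectories the state machine must agree with an independent brute-force
tracker (a regular-expression scan over per-frame region labels) across
20 seeds.

Conductance is the closed form C = N·z·e/(t·V); fractional N is accepted
because published rates are means over repeats.  Summaries over repeats
are the unweighted mean and sample SD (ddof=1).

## Pore-radius profiles

At each z level the reported radius is max over in-plane centres of
min over atoms of (distance − vdW radius), capped at `max_radius`
(default 10 Å) and constrained to a search disc (default 4 Å) around the
axis — an in-plane maximal inscribed sphere.  The maximiser is 8-start
Nelder–Mead (first start on the axis, the rest uniform in the disc,
seeded; tolerance 0.01 Å); any maximiser agreeing with the analytic oracle
is acceptable, and annealing was not needed.  Default vdW radii: C 1.70,
N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å; hydrogens are included when the
topology has them.  Levels with no atoms in capture range report the cap
and are flagged.

The oracle is the ring-built toy pore: atoms of radius r on circles of
radius R(z)+r make the exact on-axis inscribed radius

    R*(z) = minᵢ √((R(zᵢ)+r)² + (z−zᵢ)²) − r,

which also captures the cross-ring narrowing near steep profile changes.
With ring spacing 0.5 Å (≤ atom radius) and ≥6 atoms per ring the
between-ring bulge stays below the 0.05 Å validation tolerance down to a
1 Å throat.  Recovered profiles match this oracle to <0.05 Å on constant,
stepped and hourglass pores, and are rotation- and translation-invariant.

Filter geometry: per-frame minimum heavy-atom (element ≠ H) pair distance
between two selections under minimum image, validated against 27-image
enumeration; γ-carbon pairs are expressed by selecting `name CG`
explicitly.  Distance densities are normalised histograms; modes are local
maxima above a 5%-of-peak prominence, and two or more modes flag
bimodality.

## Solvation and proximity

Coordination numbers count water oxygens (or any partner selection)
strictly within the cutoff (default 4.5 Å — the first minimum of the bulk
ion–water-oxygen RDF).  The strict `<` convention is a measure-zero choice
made for determinism and is documented wherever it could matter.  The RDF
uses the standard ideal-gas shell normalisation; its first minimum is the
first local minimum after the first maximum, refined by quadratic
interpolation; fewer than 100 pair samples triggers a warning.

The knock-on statistic: per frame, the ion bound at the filter is the
species ion inside `z_sf ± 2 Å` (configurable) and inside the cylinder —
frames with none are skipped, ties resolved toward the band centre — and
the reported distribution is the distance to the nearest same-species ion
on the luminal side, with P(d < 7 Å) and the modal distance.  With no
luminal partner in any frame the probability is reported as unavailable
rather than zero.

For multisite divalent-ion models the central particle is taken as the
ion position; satellite particles are force-field constructs.

## Density maps

Atoms are binned by floor((pos−origin)/spacing) into voxels, one voxel per
atom observation; out-of-bounds atoms are tallied as overflow so that
Σ counts is exactly the number of in-bounds observations — conservation is
asserted, not approximated.  Density is counts/(n_frames·voxel volume) in
ions·Å⁻³ (number density; the normalisation is labelled since molarity is
also common).  Optional least-squares (Kabsch) alignment on a protein
selection precedes binning; it is off by default because restrained
proteins do not drift, but required for unrestrained input.  OpenDX I/O
round-trips to 1e-6 relative.

## Umbrella sampling and WHAM

Window files are two-column (time, ξ) plain text plus a manifest
(path, ξ0, k, equilibration cut); the first 2 ns are discarded by default.
WHAM iterates the standard self-consistency from f_i = 0 with histogram
bin 0.2 Å (must resolve 1 Å window spacing), converging on
max |Δf_i| < 1e-7 kcal/mol; non-convergence and broken window chains
(sample-range union disconnected) are hard errors, while adjacent windows
sharing no histogram bin only warn.  Empty interior bins yield NaN free
energies rather than aborting the solve.  The profile is zeroed at its
global minimum (a bulk-reference zero is available).

Bootstrap errors resample each window's samples i.i.d. with replacement
(no block bootstrap by default, matching the plain 100-replicate
treatment; correlation-aware blocking is future work), re-run WHAM on the
full-data bin grid warm-started from the full-data window free energies,
re-zero each replicate, and report per-bin SDs.  Everything is seeded.

The synthetic sampler draws from the biased Boltzmann density by
vectorised random-walk Metropolis (64 parallel walkers, 500-step burn-in
with the proposal step tuned toward 30–50% acceptance, thinning 5, hard
domain walls).  Validation: unbiased flat-surface samples pass a KS test
against uniform; a biased harmonic surface reproduces the closed-form
Gaussian variance kBT/(k0+k); and on a double-well with an 8 kcal/mol
barrier — the scale of a closed selectivity filter — 58 windows at 1 Å
spacing × 5000 samples recover the barrier to <0.3 kcal/mol across seeds,
with flat-profile ripple ≤0.1 kcal/mol at 10⁵ samples.

Observable-vs-ξ profiles (e.g. hydration during permeation) are assembled
either as per-window statistics plotted at ξ0 or by pooling samples binned
by sampled ξ; the two agree for narrow windows and both are provided.

## The synthetic generator: what it does and does not emulate

The drift–diffusion generator is overdamped Langevin (Euler–Maruyama,
per-axis variance 2·D·dt) with a constant luminal→cytosolic drift inside
the pore column standing in for the applied field, plus optional
deterministic straight-line "planted" crossers and a static ring of
protein-tagged anchor atoms marking the pore centre.  Default desk-scale
conditions: 40×40×80 ų box, D = 10 Å²/ns (bulk-ion scale), drift
30 Å/ns, 100–400 frames at 0.1 ns spacing mirroring the study's 100 ps
save interval.  With D = 0 the planted count is exactly the total crossing
count by construction, which is what makes event-detection exactness
testable.

It does **not** emulate electrostatics, ion–ion correlation, a membrane,
protein flexibility, or realistic barrier heights; synthetic water is lone
oxygen atoms since every implemented definition counts water oxygens only.
Passing tests therefore demonstrate that the *measurement* layer is exact
and self-consistent on known ground truth — not that any particular
physical conductance value would be reproduced from real trajectories.
Real MD input exercises exactly the same code paths through the
PDB/GRO/XTC/DCD readers.

## Degenerate inputs and tie-breaks

Empty selections are legal for `select` but rejected where an analysis
needs atoms; identical selections are rejected for minimum pair distances
(degenerate zero).  Zero voltage and non-positive times are errors in the
conductance formula.  An open geometry that bounds the probe sphere only
on the axis (two isolated atoms) is profiled with a zero search disc.
Ions exactly on a cutoff or plane fall on the strict-inequality side, by
convention, everywhere.

## Problem sizes used in validation

Desk-scale sizes keep the full suite and the acceptance script at minutes
on one CPU: 21 planted-count runs (80 frames), 20 diffusive oracle seeds
(150 frames, 10 ions), three toy pores (~800 atoms, 25 levels), WHAM at
5 × 58 windows × 5000 samples plus one 100-replicate bootstrap, and a
10⁵-sample flat-profile check.  These sizes were chosen as the smallest at
which the stated tolerances are meaningful rather than noise-dominated.
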