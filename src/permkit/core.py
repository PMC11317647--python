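"""Shared domain types and trajectory I/O.

The central container is :class:`Trajectory`: an ordered list of frames of
atom positions (Å) in an orthorhombic periodic box, plus a static per-atom
topology carrying a *species tag* for each atom.  Species tags
(``protein``, ``water-oxygen``, ``water-other``, ``cation``, ``anion``,
``other``) are what the analysis modules select on; they are assigned from
residue/atom-name rules when a file is loaded.

File reading and writing is delegated to MDAnalysis (PDB/GRO topologies;
XTC/DCD/multi-frame-PDB coordinates); this module only converts between
MDAnalysis Universes and permkit's lightweight arrays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SPECIES_TAGS = (
    "protein",
    "water-oxygen",
    "water-other",
    "cation",
    "anion",
    "other",
)

#: Default residue/atom-name rules for species assignment.  Each entry maps a
#: tag to (resnames, atom-names); an empty name set means "any atom name".
DEFAULT_SPECIES_RULES: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "water-oxygen": (
        frozenset({"SOL", "TIP3", "TIP3P", "HOH", "WAT", "TIP4", "SPC"}),
        frozenset({"OW", "OH2", "O"}),
    ),
    "water-other": (
        frozenset({"SOL", "TIP3", "TIP3P", "HOH", "WAT", "TIP4", "SPC"}),
        frozenset(),
    ),
    "cation": (
        frozenset({"NA", "SOD", "CA", "CAL", "K", "POT", "MG", "CA2", "ION"}),
        frozenset({"NA", "SOD", "CA", "CAL", "K", "POT", "MG"}),
    ),
    "anion": (
        frozenset({"CL", "CLA"}),
        frozenset({"CL", "CLA"}),
    ),
}

_AMINO = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)


@dataclass(frozen=True)
class Frame:
    """One snapshot: time (ns), positions (N, 3) in Å, orthorhombic box (3,) in Å."""

    time: float
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        box = np.asarray(self.box, dtype=float).reshape(3)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "box", box)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError(f"positions must be (N, 3), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if not np.all(box > 0):
            raise ValueError(f"box lengths must be > 0, got {box}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class Topology:
    """Static per-atom records: names, elements, residues, chains, species tags."""

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    species: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        for f in ("names", "elements", "resnames", "chains", "species"):
            arr = np.asarray(getattr(self, f), dtype=object).astype(str)
            object.__setattr__(self, f, arr)
            if len(arr) != n:
                raise ValueError(f"topology field {f!r} has length {len(arr)} != {n}")
        object.__setattr__(self, "resids", np.asarray(self.resids, dtype=int))
        if len(self.resids) != n:
            raise ValueError("resids length mismatch")
        bad = set(self.species) - set(SPECIES_TAGS)
        if bad:
            raise ValueError(f"unknown species tags: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    Invariants: every frame has the topology's atom count, and frame times
    strictly increase.  ``dt`` is the nominal frame spacing in ns.
    """

    frames: list[Frame]
    topology: Topology
    dt: float = 0.1

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {fr.n_atoms} atoms but topology has {n}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must strictly increase")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def positions(self) -> np.ndarray:
        """All positions stacked as (n_frames, n_atoms, 3)."""
        return np.stack([fr.positions for fr in self.frames])

    def sliced(self, start: int = 0, stop: int | None = None, stride: int = 1) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(self.frames[start:stop:stride], self.topology,
                          dt=self.dt * stride)


@dataclass(frozen=True)
class PoreSpec:
    """Geometric contract shared by all pore analyses.

    The pore is a cylinder of radius ``cylinder_radius`` (default 6 Å) around
    ``axis`` (default +z), centred on the per-frame centre of mass of the
    atoms matched by ``center_selection`` (or the box centre when None).
    ``z_sf`` and ``z_gate`` locate the selectivity-filter and cytosolic-gate
    planes along the axis, relative to the centre; ``luminal_side=+1`` puts
    the lumen at larger axial coordinate.
    """

    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    center_selection: str | None = None
    cylinder_radius: float = 6.0
    z_sf: float = 10.0
    z_gate: float = -10.0
    luminal_side: int = 1

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(ax), 1.0, atol=1e-6):
            raise ValueError(f"axis must have unit norm, got {ax}")
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder_radius must be > 0")
        if self.z_gate == self.z_sf:
            raise ValueError("z_gate must differ from z_sf")
        if self.luminal_side not in (-1, 1):
            raise ValueError("luminal_side must be +1 or -1")

    @property
    def axis_vec(self) -> np.ndarray:
        return np.asarray(self.axis, dtype=float)


@dataclass(frozen=True)
class AnalysisParams:
    """Cross-module analysis parameters with the study's conventions as defaults."""

    coordination_cutoff: float = 4.5
    proximity_threshold: float = 7.0
    density_grid_spacing: float = 1.0
    histogram_bin: float = 0.25
    temperature: float = 310.0

    def __post_init__(self) -> None:
        for f in (
            "coordination_cutoff",
            "proximity_threshold",
            "density_grid_spacing",
            "histogram_bin",
            "temperature",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")


# ---------------------------------------------------------------------------
# periodic-box geometry helpers
# ---------------------------------------------------------------------------

def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors (orthorhombic)."""
    disp = np.asarray(disp, dtype=float)
    box = np.asarray(box, dtype=float)
    return disp - box * np.round(disp / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distances between position arrays of matching shape."""
    d = minimum_image(np.asarray(a) - np.asarray(b), box)
    return np.linalg.norm(d, axis=-1)


def wrap_positions(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap positions into the primary box [0, L)."""
    box = np.asarray(box, dtype=float)
    return np.mod(pos, box)


def unwrap_series(coord: np.ndarray, length: float) -> np.ndarray:
    """Unwrap a 1D coordinate time series across a periodic length.

    Successive jumps larger than half the box are interpreted as wrapping
    events and removed, yielding a continuous path.
    """
    coord = np.asarray(coord, dtype=float)
    if coord.size < 2:
        return coord.copy()
    d = np.diff(coord)
    d -= length * np.round(d / length)
    return np.concatenate([[coord[0]], coord[0] + np.cumsum(d)])


def center_of_mass_series(
    traj: Trajectory, indices: np.ndarray | None, axis: np.ndarray
) -> np.ndarray:
    """Axial coordinate of the (unweighted) centre of the given atoms per frame.

    With ``indices`` None the box centre is used.  The centre's own axial
    path is unwrapped so that slow drift of the reference does not fold back
    through the periodic boundary.  Masses are not used: the pore-forming
    selections this anchors are compact heavy-atom groups for which the
    geometric centre and the centre of mass are interchangeable at the
    sub-Å level.
    """
    ax = np.asarray(axis, dtype=float)
    vals = np.empty(traj.n_frames)
    for i, fr in enumerate(traj.frames):
        if indices is None or len(indices) == 0:
            c = fr.box / 2.0
        else:
            # cluster around the first atom under minimum image, then average
            ref = fr.positions[indices[0]]
            rel = minimum_image(fr.positions[indices] - ref, fr.box)
            c = ref + rel.mean(axis=0)
        vals[i] = float(c @ ax)
    if traj.n_frames > 1:
        L = float(traj.frames[0].box @ np.abs(ax))
        vals = unwrap_series(vals, L)
    return vals


# ---------------------------------------------------------------------------
# species assignment and file I/O
# ---------------------------------------------------------------------------

def assign_species(
    names: Sequence[str],
    resnames: Sequence[str],
    rules: Mapping[str, tuple[Iterable[str], Iterable[str]]] | None = None,
) -> np.ndarray:
    """Assign a species tag to each atom from residue/atom-name rules.

    Order of precedence: water-oxygen before water-other (both match water
    residues), then cation/anion, then protein (standard amino-acid residue
    names), then ``other``.  Unassignable atoms default to ``other``; the
    count is logged as a warning.
    """
    rule_map = dict(DEFAULT_SPECIES_RULES)
    if rules:
        for tag, (rn, an) in rules.items():
            if tag not in SPECIES_TAGS:
                raise ValueError(f"unknown species tag {tag!r}")
            rule_map[tag] = (frozenset(map(str.upper, rn)), frozenset(map(str.upper, an)))

    out = np.empty(len(names), dtype=object)
    n_other = 0
    for i, (name, resname) in enumerate(zip(names, resnames)):
        nm, rs = str(name).upper(), str(resname).upper()
        tag = None
        for candidate in ("water-oxygen", "water-other", "cation", "anion"):
            resnames_ok, names_ok = rule_map[candidate]
            if rs in resnames_ok and (not names_ok or nm in names_ok):
                tag = candidate
                break
        if tag is None and rs in _AMINO:
            tag = "protein"
        if tag is None:
            tag = "other"
            n_other += 1
        out[i] = tag
    if n_other:
        logger.warning("%d atoms could not be classified; tagged 'other'", n_other)
    return out.astype(str)


def _element_from_name(name: str) -> str:
    for ch in str(name):
        if ch.isalpha():
            return ch.upper()
    return "X"


def load_trajectory(
    topology_path: str | Path,
    coords_path: str | Path | None = None,
    species_rules: Mapping | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Load a trajectory from disk into a :class:`Trajectory`.

    Parameters
    ----------
    topology_path : PDB or GRO file defining atoms.
    coords_path : XTC, DCD or multi-frame PDB with coordinates; when omitted
        the topology file's own frames are used.
    species_rules : optional overrides for :func:`assign_species`.
    dt : frame spacing in ns; inferred from the file when possible.

    Raises
    ------
    FileNotFoundError, ValueError
        Missing files, or an atom-count mismatch between topology and
        coordinates (the error names both counts).
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FileNotFoundError(f"topology file not found: {topology_path}")
    if coords_path is not None:
        coords_path = Path(coords_path)
        if not coords_path.exists():
            raise FileNotFoundError(f"coordinate file not found: {coords_path}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if coords_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(coords_path))
        except ValueError as err:
            msg = str(err)
            if "atoms" in msg and ("number" in msg or "mismatch" in msg.lower()):
                n_top = len(mda.Universe(str(topology_path)).atoms)
                raise ValueError(
                    f"atom count mismatch: topology {topology_path} has {n_top} "
                    f"atoms but coordinates {coords_path} disagree ({msg})"
                ) from err
            raise

    names = u.atoms.names
    resnames = u.atoms.resnames
    resids = u.atoms.resids
    try:
        chains = u.atoms.segids
    except Exception:  # pragma: no cover - topology without segments
        chains = np.array(["A"] * len(names))
    try:
        elements = u.atoms.elements
    except Exception:
        elements = np.array([_element_from_name(n) for n in names])

    top = Topology(
        names=names,
        elements=elements,
        resnames=resnames,
        resids=resids,
        chains=chains,
        species=assign_species(names, resnames, species_rules),
    )

    frames: list[Frame] = []
    file_dt = None
    prev_t = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            t_ns = float(ts.time) / 1000.0  # MDAnalysis times are ps
            if prev_t is not None and t_ns <= prev_t:
                t_ns = prev_t + (file_dt or 0.1)
            if prev_t is not None and file_dt is None:
                file_dt = t_ns - prev_t
            box = np.asarray(ts.dimensions[:3], dtype=float)
            if not np.all(box > 0):
                box = np.array([1000.0, 1000.0, 1000.0])
            frames.append(
                Frame(time=t_ns, positions=ts.positions.astype(float), box=box)
            )
            prev_t = t_ns
    if dt is None:
        dt = file_dt if file_dt else 0.1
    return Trajectory(frames=frames, topology=top, dt=dt)


def write_trajectory(
    traj: Trajectory,
    topology_path: str | Path,
    coords_path: str | Path | None = None,
) -> None:
    """Write a trajectory to standard formats via MDAnalysis.

    ``topology_path`` (GRO or PDB) receives the first frame; ``coords_path``
    (XTC, DCD or multi-frame PDB), when given, receives all frames.
    """
    import MDAnalysis as mda

    n = traj.n_atoms
    top = traj.topology
    n_res = len(np.unique(top.resids))
    # map residues preserving first-appearance order
    _, res_index = np.unique(top.resids, return_index=True)
    order = np.sort(res_index)
    uniq_resids = top.resids[order]
    resid_to_ix = {r: i for i, r in enumerate(uniq_resids)}
    atom_res = np.array([resid_to_ix[r] for r in top.resids])

    u = mda.Universe.empty(
        n, n_residues=n_res, atom_resindex=atom_res, trajectory=True
    )
    u.add_TopologyAttr("names", top.names)
    u.add_TopologyAttr("resnames", top.resnames[order])
    u.add_TopologyAttr("resids", uniq_resids)
    u.add_TopologyAttr("elements", top.elements)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.positions = traj.frames[0].positions
        u.dimensions = [*traj.frames[0].box, 90.0, 90.0, 90.0]
        u.atoms.write(str(topology_path))
        if coords_path is not None:
            with mda.Writer(str(coords_path), n_atoms=n) as w:
                for fr in traj.frames:
                    u.atoms.positions = fr.positions
                    u.dimensions = [*fr.box, 90.0, 90.0, 90.0]
                    u.trajectory.ts.time = fr.time * 1000.0  # ns -> ps
                    w.write(u.atoms)
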