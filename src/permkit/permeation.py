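"""Permeation-event detection, conductance, and permeability ratios.

A permeation event is one ion traversing the pore from the luminal side,
through the cylinder that encloses the conduction pathway, past the
cytosolic gate.  Detection runs a per-ion finite-state machine over the
ion's axial position relative to the per-frame pore centre: the ion must
start in the luminal bulk (beyond the SF plane plus a hysteresis margin),
stay inside the cylinder radius on every frame while between the planes
(strict mode, the default), and reach the cytosolic bulk (past the gate
plane plus margin).  Ions that enter and retreat, or that leave the
cylinder radially mid-pore, emit nothing; re-entrant ions can emit multiple
events.  Reverse (cytosolic→luminal) traversals are recorded with
direction −1 and excluded from the conductance count.

Conductance follows C = N_event·Q_ion / (t·V_tm): with N events of ions of
valence z over t ns under V mV, C[pS] = N·z·1.602177×10⁵ / (t·V).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._units import COND_PS
from .core import SPECIES_TAGS, PoreSpec, Trajectory, minimum_image
from .selections import select

logger = logging.getLogger(__name__)

__all__ = [
    "PermeationEvent",
    "ConductanceEstimate",
    "detect_events",
    "cumulative_counts",
    "conductance",
    "conductance_summary",
    "permeability_ratio",
    "format_ratio",
    "events_to_frame",
]

#: Default valence by (upper-cased) atom/residue name.
DEFAULT_CHARGES = {"NA": 1, "SOD": 1, "K": 1, "POT": 1, "CA": 2, "CAL": 2,
                   "MG": 2, "CL": -1, "CLA": -1}


@dataclass(frozen=True)
class PermeationEvent:
    """One full directional traversal.

    ``t_entry`` is the last time the ion was in the bulk it came from before
    the traversal; ``t_cross`` the first frame past the far plane.
    ``direction`` is +1 for luminal→cytosolic, −1 for the reverse.
    """

    atom: int
    species: str
    charge: int
    t_entry: float
    t_cross: float
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.t_cross < self.t_entry:
            raise ValueError("t_cross must be >= t_entry")


@dataclass
class ConductanceEstimate:
    """Per-repeat conductances (pS) and their unweighted mean and sample SD."""

    per_repeat: np.ndarray
    mean: float
    sd: float


def _axial_frames(traj: Trajectory, pore: PoreSpec, center_idx: np.ndarray | None):
    """Per-frame pore centre (3-vector) clustered under minimum image."""
    centers = np.empty((traj.n_frames, 3))
    for i, fr in enumerate(traj.frames):
        if center_idx is None or len(center_idx) == 0:
            centers[i] = fr.box / 2.0
        else:
            ref = fr.positions[center_idx[0]]
            rel = minimum_image(fr.positions[center_idx] - ref, fr.box)
            centers[i] = ref + rel.mean(axis=0)
    return centers


def detect_events(
    traj: Trajectory,
    pore: PoreSpec,
    species: str = "cation",
    stride: int = 1,
    margin: float = 2.0,
    strict_cylinder: bool = True,
    charges: dict[str, int] | None = None,
) -> list[PermeationEvent]:
    """Detect directional permeation events of a species.

    Parameters
    ----------
    species : a species tag (``cation``, ``anion``, ``water-oxygen``, ...)
        or any selection expression.
    stride : analyse every ``stride``-th frame (must be ≥ 1).
    margin : hysteresis (Å) added beyond each plane before an ion counts as
        "in bulk", suppressing chatter for ions sitting on a plane.
    strict_cylinder : if True (default) the ion must satisfy the radial
        cylinder test on every frame between the planes; if False only on
        its last in-pore frame before crossing.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sub = traj.sliced(stride=stride) if stride > 1 else traj
    if species in SPECIES_TAGS:
        ion_idx = np.flatnonzero(sub.topology.species == species)
    else:
        ion_idx = select(sub, species)
    if len(ion_idx) == 0:
        warnings.warn(f"no atoms match species {species!r}; no events detected",
                      stacklevel=2)
        return []
    if sub.n_frames < 2:
        raise ValueError("event detection needs at least 2 frames")

    charge_map = dict(DEFAULT_CHARGES)
    if charges:
        charge_map.update({k.upper(): v for k, v in charges.items()})

    center_idx = (
        select(sub, pore.center_selection) if pore.center_selection else None
    )
    centers = _axial_frames(sub, pore, center_idx)
    ax = pore.axis_vec
    s = pore.luminal_side
    u_sf, u_gate = s * pore.z_sf, s * pore.z_gate
    if u_sf <= u_gate:
        raise ValueError(
            "PoreSpec inconsistent with luminal_side: the SF plane must lie "
            "on the luminal side of the gate plane"
        )

    times = sub.times
    pos = sub.positions()  # (n_frames, n_atoms, 3)
    boxes = np.stack([fr.box for fr in sub.frames])

    events: list[PermeationEvent] = []
    for atom in ion_idx:
        rel = minimum_image(pos[:, atom, :] - centers, boxes)
        u = s * (rel @ ax)
        radial = np.linalg.norm(rel - np.outer(rel @ ax, ax), axis=1)

        came_from = 0  # +1 luminal, -1 cytosolic, 0 unknown
        valid = True
        t_entry = times[0]
        r_last_mid = np.inf
        for fi in range(sub.n_frames):
            if u[fi] > u_sf + margin:  # luminal bulk
                if came_from == -1 and valid and r_last_mid <= pore.cylinder_radius:
                    events.append(PermeationEvent(
                        atom=int(atom),
                        species=str(sub.topology.species[atom]),
                        charge=charge_map.get(
                            str(sub.topology.names[atom]).upper(), 1),
                        t_entry=float(t_entry), t_cross=float(times[fi]),
                        direction=-1))
                came_from, valid, t_entry = 1, True, times[fi]
                r_last_mid = np.inf
            elif u[fi] < u_gate - margin:  # cytosolic bulk
                if came_from == 1 and valid and r_last_mid <= pore.cylinder_radius:
                    events.append(PermeationEvent(
                        atom=int(atom),
                        species=str(sub.topology.species[atom]),
                        charge=charge_map.get(
                            str(sub.topology.names[atom]).upper(), 1),
                        t_entry=float(t_entry), t_cross=float(times[fi]),
                        direction=1))
                came_from, valid, t_entry = -1, True, times[fi]
                r_last_mid = np.inf
            else:  # between the bulk regions
                r_last_mid = radial[fi]
                if strict_cylinder and radial[fi] > pore.cylinder_radius:
                    valid = False  # left the pore radially: restart
    events.sort(key=lambda e: e.t_cross)
    return events


def cumulative_counts(
    events: list[PermeationEvent],
    t_grid: np.ndarray,
    direction: int = 1,
) -> np.ndarray:
    """Cumulative number of events of the given direction at each grid time."""
    t_grid = np.asarray(t_grid, dtype=float)
    t_cross = np.sort([e.t_cross for e in events if e.direction == direction])
    return np.searchsorted(t_cross, t_grid, side="right").astype(int)


def conductance(n_events: float, z: float, t_ns: float, v_mv: float) -> float:
    """Single-trajectory conductance in pS: C = N·z·e / (t·V).

    ``n_events`` may be fractional (a mean over repeats).  Raises on
    non-positive time or zero voltage.
    """
    if t_ns <= 0:
        raise ValueError("trajectory length must be positive")
    if v_mv == 0:
        raise ValueError("conductance is undefined at zero transmembrane voltage")
    return n_events * z * COND_PS / (t_ns * v_mv)


def conductance_summary(per_repeat: list[float] | np.ndarray) -> ConductanceEstimate:
    """Unweighted mean and sample SD over per-repeat conductances (pS)."""
    arr = np.asarray(per_repeat, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return ConductanceEstimate(per_repeat=arr, mean=float(arr.mean()), sd=sd)


def permeability_ratio(rate_a: float, rate_b: float) -> float:
    """Ratio of event rates of two species under identical conditions."""
    if rate_b <= 0:
        raise ValueError("reference rate must be positive")
    return rate_a / rate_b


def format_ratio(ratio: float) -> str:
    """Render a permeability ratio as 'x.x:1'."""
    return f"{ratio:.1f}:1"


def events_to_frame(events: list[PermeationEvent]) -> pd.DataFrame:
    """Tabulate events (atom, species, t_entry_ns, t_cross_ns, direction)."""
    return pd.DataFrame(
        [
            {
                "atom": e.atom,
                "species": e.species,
                "charge": e.charge,
                "t_entry_ns": e.t_entry,
                "t_cross_ns": e.t_cross,
                "direction": e.direction,
            }
            for e in events
        ],
        columns=["atom", "species", "charge", "t_entry_ns", "t_cross_ns", "direction"],
    )
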