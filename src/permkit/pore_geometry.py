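"""Pore-radius profiles and selectivity-filter geometry.

The pore radius at an axial level z is the radius of the largest sphere
centred in the plane at z that overlaps no protein atom — i.e. the maximum
over in-plane centre positions c of

    min_a ( |p_a − c| − vdw_a ),

capped at ``max_radius``.  The maximisation uses seeded multi-start
Nelder–Mead searches within a disc around the pore axis (the original
Monte-Carlo-annealing flavour of this algorithm is not required; any
maximiser that matches the analytic toy-pore oracle is acceptable).

Selectivity-filter geometry is measured as per-frame minimum heavy-atom
distances between residue selections on different subunits (minimum-image),
or as γ-carbon pair distances, with probability-density summaries and
bimodality detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import find_peaks

from .core import Frame, PoreSpec, Trajectory, minimum_image
from .selections import select

__all__ = [
    "DEFAULT_VDW",
    "RadiusProfile",
    "DistanceSeries",
    "radius_profile",
    "mean_radius_profile",
    "combine_profiles",
    "min_pair_distance",
    "pair_distance_distribution",
]

#: Default van der Waals radii (Å) by element.
DEFAULT_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
               "P": 1.80, "X": 1.50}


@dataclass
class RadiusProfile:
    """Mean pore radius vs axial position, with SD across frames/repeats."""

    z: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    flagged: np.ndarray | None = None  # levels where the empty-slice cap fired

    def __post_init__(self) -> None:
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z grid must strictly increase")
        if np.any(self.mean < 0):
            raise ValueError("radii must be non-negative")

    def min_radius(self) -> tuple[float, float]:
        """(z at the constriction, radius there)."""
        i = int(np.argmin(self.mean))
        return float(self.z[i]), float(self.mean[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_A": self.z, "mean_radius_A": self.mean,
                             "sd_A": self.sd})


@dataclass
class DistanceSeries:
    """A labelled distance time series (Å), e.g. one SF residue pair."""

    label: str
    times: np.ndarray
    values: np.ndarray
    reference: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(self.values <= 0):
            raise ValueError("distances must be positive")


def _clearance(centers_xy: np.ndarray, z: float, atom_pos: np.ndarray,
               atom_vdw: np.ndarray, cap: float) -> np.ndarray:
    """min over atoms of (distance − vdw) for each candidate centre."""
    c = np.column_stack([
        centers_xy,
        np.full(len(centers_xy), z),
    ])
    d = np.linalg.norm(atom_pos[None, :, :] - c[:, None, :], axis=2) - atom_vdw[None, :]
    return np.minimum(d.min(axis=1), cap)


def radius_profile(
    frame: Frame,
    protein_indices: np.ndarray,
    elements: np.ndarray,
    axis_xy: tuple[float, float],
    z_range: tuple[float, float],
    z_step: float = 0.5,
    vdw_table: dict[str, float] | None = None,
    max_radius: float = 10.0,
    search_radius: float = 4.0,
    n_starts: int = 8,
    seed: int = 0,
    tol: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-frame maximal-inscribed-sphere profile.

    Returns (z levels, radii, flagged) where ``flagged`` marks levels with
    no atoms in capture range (radius reported as the ``max_radius`` cap).
    ``axis_xy`` is the in-plane position of the (straight) pore axis;
    ``z_range`` is in absolute frame coordinates.
    """
    vdw = dict(DEFAULT_VDW)
    if vdw_table:
        vdw.update(vdw_table)
    if len(protein_indices) == 0:
        raise ValueError("protein selection is empty")
    pos = frame.positions[protein_indices]
    radii_a = np.array([vdw.get(str(e).upper(), 1.5) for e in elements[protein_indices]])
    vdw_max = radii_a.max()

    rng = np.random.default_rng(seed)
    z_levels = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    out = np.empty(len(z_levels))
    flagged = np.zeros(len(z_levels), dtype=bool)
    x0, y0 = axis_xy
    # fixed multi-start offsets per profile call (seeded once, reused per level)
    offsets = np.vstack([
        [0.0, 0.0],
        rng.uniform(-search_radius, search_radius, size=(max(n_starts - 1, 0), 2)),
    ])
    for li, z in enumerate(z_levels):
        near = np.abs(pos[:, 2] - z) <= (max_radius + vdw_max)
        if not near.any():
            out[li] = max_radius
            flagged[li] = True
            continue
        p_near = pos[near]
        v_near = radii_a[near]

        def neg_clearance(c_xy):
            d = np.linalg.norm(p_near - np.array([c_xy[0], c_xy[1], z]), axis=1)
            clear = min(float((d - v_near).min()), max_radius)
            # keep the sphere centre inside the search disc around the axis
            off = np.hypot(c_xy[0] - x0, c_xy[1] - y0) - search_radius
            if off > 0:
                clear -= 10.0 * off
            return -clear

        best = -np.inf
        for off in offsets:
            res = minimize(
                neg_clearance,
                np.array([x0, y0]) + off,
                method="Nelder-Mead",
                options={"xatol": tol, "fatol": tol * 0.1, "maxiter": 400},
            )
            best = max(best, -res.fun)
        out[li] = min(max(best, 0.0), max_radius)
    return z_levels, out, flagged


def mean_radius_profile(
    trajs: Trajectory | list[Trajectory],
    protein_selection: str,
    pore: PoreSpec,
    z_range: tuple[float, float],
    z_step: float = 0.5,
    window: tuple[float, float] | float | None = None,
    stride: int = 1,
    relative_z: bool = True,
    **profile_kwargs,
) -> RadiusProfile:
    """Per-frame profiles averaged over a time window and over repeats.

    ``window`` selects frames: a (t0, t1) interval in ns, or a fraction f in
    (0, 1] meaning "the last f of the run" (e.g. 0.6 → the last 60% of
    frames, how mean profiles over the tail of a trajectory are typically
    reported).  ``z_range`` is relative to the pore centre when
    ``relative_z`` (the default).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    profiles = []
    for traj in trajs:
        sel = select(traj, protein_selection)
        if len(sel) == 0:
            raise ValueError(f"selection {protein_selection!r} matched no atoms")
        times = traj.times
        if window is None:
            keep = np.ones(traj.n_frames, dtype=bool)
        elif np.isscalar(window):
            if not 0 < window <= 1:
                raise ValueError("fractional window must be in (0, 1]")
            n_keep = int(round(window * traj.n_frames))
            keep = np.zeros(traj.n_frames, dtype=bool)
            keep[traj.n_frames - n_keep :] = True
        else:
            keep = (times >= window[0]) & (times <= window[1])
        frame_ix = np.flatnonzero(keep)[::stride]
        if len(frame_ix) == 0:
            raise ValueError("time window selects no frames")
        for fi in frame_ix:
            fr = traj.frames[fi]
            ref = fr.positions[sel[0]]
            rel = minimum_image(fr.positions[sel] - ref, fr.box)
            com = ref + rel.mean(axis=0)
            zr = (z_range[0] + com[2], z_range[1] + com[2]) if relative_z else z_range
            z, r, fl = radius_profile(
                fr, sel, traj.topology.elements, (com[0], com[1]), zr,
                z_step=z_step, **profile_kwargs,
            )
            profiles.append(r)
    stack = np.vstack(profiles)
    z_rel = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    sd = np.std(stack, axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(stack.shape[1])
    return RadiusProfile(z=z_rel, mean=stack.mean(axis=0), sd=sd)


def combine_profiles(profiles: list[np.ndarray], z: np.ndarray) -> RadiusProfile:
    """Mean and sample SD across per-repeat (or per-frame) profiles."""
    stack = np.vstack(profiles)
    sd = np.std(stack, axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(stack.shape[1])
    return RadiusProfile(z=np.asarray(z), mean=stack.mean(axis=0), sd=sd)


def min_pair_distance(
    traj: Trajectory,
    selection_a: str,
    selection_b: str,
    stride: int = 1,
    heavy_only: bool = True,
    label: str | None = None,
    reference: float | None = None,
) -> DistanceSeries:
    """Per-frame minimum atom-pair distance between two selections.

    Distances obey the minimum-image convention; hydrogens are excluded by
    default ("heavy-atom minimum").  Identical selections are rejected.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    ia = select(traj, selection_a)
    ib = select(traj, selection_b)
    if heavy_only:
        heavy = np.char.upper(traj.topology.elements.astype(str)) != "H"
        ia = ia[heavy[ia]]
        ib = ib[heavy[ib]]
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("selection matched no (heavy) atoms")
    if np.array_equal(ia, ib):
        raise ValueError("selections are identical; minimum distance is degenerate")
    times, values = [], []
    for fr in traj.frames[::stride]:
        d = minimum_image(
            fr.positions[ia][:, None, :] - fr.positions[ib][None, :, :], fr.box
        )
        values.append(float(np.linalg.norm(d, axis=2).min()))
        times.append(fr.time)
    return DistanceSeries(
        label=label or f"{selection_a} × {selection_b}",
        times=np.array(times), values=np.array(values), reference=reference,
    )


def pair_distance_distribution(
    values: np.ndarray | tuple[np.ndarray, np.ndarray],
    bins: int | np.ndarray = 50,
    range: tuple | None = None,
    prominence: float = 0.05,
) -> dict:
    """Normalised probability density of one or two distance series.

    For a single series returns bin centres, a density integrating to 1, the
    modes (local maxima above ``prominence`` × peak density), and a
    bimodality flag.  A tuple of two series yields a joint 2D density
    (integrating to 1 over the plane).
    """
    if isinstance(values, tuple):
        a, b = (np.asarray(v, dtype=float) for v in values)
        H, xe, ye = np.histogram2d(a, b, bins=bins, range=range, density=True)
        return {
            "density": H,
            "x_centers": 0.5 * (xe[:-1] + xe[1:]),
            "y_centers": 0.5 * (ye[:-1] + ye[1:]),
        }
    v = np.asarray(values, dtype=float)
    hist, edges = np.histogram(v, bins=bins, range=range, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if hist.max() > 0:
        peaks, _ = find_peaks(
            np.concatenate([[0.0], hist, [0.0]]),
            prominence=prominence * hist.max(),
        )
        modes = centers[peaks - 1]
    else:
        modes = np.array([])
    return {
        "centers": centers,
        "density": hist,
        "modes": modes,
        "bimodal": len(modes) >= 2,
    }
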