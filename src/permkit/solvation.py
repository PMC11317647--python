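"""Ion hydration, ion–protein contacts, and nearest-cation proximity.

Coordination numbers count water oxygen atoms strictly within the cutoff
(default 4.5 Å, the first minimum of the bulk ion–water-oxygen RDF) of a
tracked ion, per frame, under minimum-image distances.  The nearest-ion
("knock-on") distribution asks, for every frame with an ion bound at the
selectivity filter, how far away the nearest same-species ion on the
luminal side is — summarised as a probability density, its mode, and
P(d < threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SPECIES_TAGS, AnalysisParams, PoreSpec, Trajectory, minimum_image
from .permeation import _axial_frames
from .selections import select

__all__ = [
    "CoordinationSeries",
    "ProximityDistribution",
    "coordination_number",
    "rdf",
    "first_minimum",
    "contact_fraction",
    "nearest_ion_distribution",
]


@dataclass
class CoordinationSeries:
    """Per-frame coordination counts for one tracked ion."""

    times: np.ndarray
    counts: np.ndarray
    cutoff: float
    partner: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def min(self) -> int:
        return int(np.min(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "count": self.counts})


@dataclass
class ProximityDistribution:
    """Nearest-ion distance density with P(d < threshold) and the mode."""

    centers: np.ndarray
    density: np.ndarray
    p_below: float | None
    threshold: float
    modal_distance: float | None
    n_frames: int


def coordination_number(
    traj: Trajectory,
    ion: int,
    partner_selection: str = "species water-oxygen",
    cutoff: float = 4.5,
    stride: int = 1,
) -> CoordinationSeries:
    """Count partner atoms strictly within ``cutoff`` Å of one ion per frame."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    partners = select(traj, partner_selection)
    partners = partners[partners != ion]
    times, counts = [], []
    for fr in traj.frames[::stride]:
        d = np.linalg.norm(
            minimum_image(fr.positions[partners] - fr.positions[ion], fr.box), axis=1
        )
        counts.append(int(np.sum(d < cutoff)))
        times.append(fr.time)
    return CoordinationSeries(
        times=np.array(times), counts=np.array(counts, dtype=int),
        cutoff=cutoff, partner=partner_selection,
    )


def rdf(
    traj: Trajectory,
    selection_a: str,
    selection_b: str,
    r_max: float = 10.0,
    bin: float = 0.05,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) between two selections.

    Standard normalisation by ideal-gas shell counts: the histogram of
    minimum-image pair distances divided by N_a · n_frames · ρ_b · V_shell,
    with ρ_b the mean number density of b in the box.  Self-pairs are
    excluded when the selections share atoms.
    """
    ia = select(traj, selection_a)
    ib = select(traj, selection_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("rdf selections must be non-empty")
    edges = np.arange(0.0, r_max + bin, bin)
    hist = np.zeros(len(edges) - 1)
    n_frames = 0
    rho_sum = 0.0
    for fr in traj.frames[::stride]:
        d = np.linalg.norm(
            minimum_image(
                fr.positions[ia][:, None, :] - fr.positions[ib][None, :, :], fr.box
            ),
            axis=2,
        )
        shared = np.isin(ia, ib)
        if shared.any():
            for i, ai in enumerate(ia):
                j = np.flatnonzero(ib == ai)
                d[i, j] = np.inf
        hist += np.histogram(d[np.isfinite(d)], bins=edges)[0]
        rho_sum += len(ib) / float(np.prod(fr.box))
        n_frames += 1
    if hist.sum() < 100:
        warnings.warn("fewer than 100 pair samples; g(r) is unreliable", stacklevel=2)
    rho_b = rho_sum / n_frames
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    g = hist / (len(ia) * n_frames * rho_b * shell)
    return centers, g


def first_minimum(r: np.ndarray, g: np.ndarray, min_count_guard: int = 3) -> float | None:
    """First local minimum of g(r) after the first maximum.

    The grid minimum is refined by quadratic interpolation through the three
    surrounding points.  Returns None when no interior minimum exists.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    # first maximum: first index that is a strict local max
    imax = None
    for i in range(1, len(g) - 1):
        if g[i] >= g[i - 1] and g[i] > g[i + 1] and g[i] > 0:
            imax = i
            break
    if imax is None:
        return None
    for i in range(imax + 1, len(g) - 1):
        if g[i] <= g[i - 1] and g[i] < g[i + 1]:
            y0, y1, y2 = g[i - 1], g[i], g[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            return float(r[i] + shift * (r[1] - r[0]))
    return None


def contact_fraction(
    traj: Trajectory,
    ion_selection: str,
    residue_selection: str,
    cutoff: float = 4.5,
    stride: int = 1,
) -> tuple[float, dict[int, float]]:
    """Fraction of frames with any ion atom strictly within ``cutoff`` of the
    residue selection, plus a per-residue breakdown keyed by resid."""
    ions = select(traj, ion_selection)
    res_atoms = select(traj, residue_selection)
    if len(ions) == 0 or len(res_atoms) == 0:
        raise ValueError("contact selections must be non-empty")
    resids = traj.topology.resids[res_atoms]
    uniq = np.unique(resids)
    n_frames = 0
    any_hits = 0
    per_res = {int(r): 0 for r in uniq}
    for fr in traj.frames[::stride]:
        d = np.linalg.norm(
            minimum_image(
                fr.positions[ions][:, None, :] - fr.positions[res_atoms][None, :, :],
                fr.box,
            ),
            axis=2,
        )
        close = d < cutoff
        if close.any():
            any_hits += 1
        for r in uniq:
            if close[:, resids == r].any():
                per_res[int(r)] += 1
        n_frames += 1
    return any_hits / n_frames, {r: c / n_frames for r, c in per_res.items()}


def nearest_ion_distribution(
    traj: Trajectory,
    pore: PoreSpec,
    species: str = "cation",
    sf_band: tuple[float, float] | None = None,
    params: AnalysisParams | None = None,
    bins: int | np.ndarray = 60,
    r_range: tuple[float, float] = (0.0, 15.0),
    stride: int = 1,
) -> ProximityDistribution:
    """Distance from an SF-bound ion to the nearest luminal same-species ion.

    Per frame, the "bound" ion is the species ion inside the SF band (default
    z_sf ± 2 Å along the axis, relative to the pore centre) and inside the
    cylinder; frames with none are skipped, and with several the one closest
    to the band centre is taken.  The distance to the nearest same-species
    ion on the luminal side of the SF plane is histogrammed over qualifying
    frames; P(d < threshold) uses the strict '<' convention.
    """
    params = params or AnalysisParams()
    if sf_band is None:
        sf_band = (pore.z_sf - 2.0, pore.z_sf + 2.0)
    ions = (
        np.flatnonzero(traj.topology.species == species)
        if species in SPECIES_TAGS
        else select(traj, species)
    )
    if len(ions) < 2:
        raise ValueError("need at least two ions of the species")
    center_idx = select(traj, pore.center_selection) if pore.center_selection else None
    sub = traj.sliced(stride=stride) if stride > 1 else traj
    centers = _axial_frames(sub, pore, center_idx)
    ax = pore.axis_vec
    s = pore.luminal_side
    distances = []
    for fi, fr in enumerate(sub.frames):
        rel = minimum_image(fr.positions[ions] - centers[fi], fr.box)
        u = rel @ ax
        radial = np.linalg.norm(rel - np.outer(u, ax), axis=1)
        in_band = (
            (u >= min(sf_band)) & (u <= max(sf_band))
            & (radial <= pore.cylinder_radius)
        )
        if not in_band.any():
            continue
        band_mid = 0.5 * (sf_band[0] + sf_band[1])
        bound_local = np.flatnonzero(in_band)[
            np.argmin(np.abs(u[in_band] - band_mid))
        ]
        luminal = s * u > s * pore.z_sf
        luminal[bound_local] = False
        if not luminal.any():
            continue
        d = np.linalg.norm(
            minimum_image(
                fr.positions[ions[luminal]] - fr.positions[ions[bound_local]], fr.box
            ),
            axis=1,
        )
        distances.append(float(d.min()))
    n_q = len(distances)
    if n_q == 0:
        return ProximityDistribution(
            centers=np.array([]), density=np.array([]), p_below=None,
            threshold=params.proximity_threshold, modal_distance=None, n_frames=0,
        )
    darr = np.array(distances)
    hist, edges = np.histogram(darr, bins=bins, range=r_range, density=True)
    centers_r = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers_r[np.argmax(hist)]) if hist.max() > 0 else None
    p = float(np.mean(darr < params.proximity_threshold))
    return ProximityDistribution(
        centers=centers_r, density=hist, p_below=p,
        threshold=params.proximity_threshold, modal_distance=mode, n_frames=n_q,
    )
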