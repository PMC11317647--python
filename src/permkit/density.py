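"""Time-averaged 3D number-density maps of a species over a trajectory.

Each frame's atoms of the chosen species are binned into voxels by
floor((pos − origin) / spacing); the density is counts / (n_frames · voxel
volume), in atoms·Å⁻³.  Atoms outside the grid bounds are tallied as
overflow rather than clipped, so Σ counts equals exactly the number of
in-bounds atom observations.  OpenDX I/O goes through gridDataFormats, the
standard scalar-field interchange used by molecular viewers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import SPECIES_TAGS, Trajectory
from .selections import select

__all__ = ["DensityGrid", "density_map", "write_dx", "read_dx"]


@dataclass
class DensityGrid:
    """A voxel occupancy histogram and its normalised number density."""

    origin: np.ndarray
    spacing: np.ndarray
    counts: np.ndarray
    n_frames: int
    species: str = ""
    overflow: int = 0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if np.any(self.counts < 0):
            raise ValueError("voxel counts must be non-negative")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def density(self) -> np.ndarray:
        """Number density per voxel (atoms · Å⁻³)."""
        return self.counts / (self.n_frames * self.voxel_volume)


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation+translation mapping mobile onto ref."""
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, rc - R @ mc


def density_map(
    traj: Trajectory,
    species: str = "cation",
    bounds: tuple[tuple[float, float], ...] | None = None,
    spacing: float | tuple[float, float, float] = 1.0,
    align_selection: str | None = None,
    stride: int = 1,
) -> DensityGrid:
    """Per-voxel time-averaged occupancy of a species.

    ``bounds`` is ((x0,x1),(y0,y1),(z0,z1)) in Å; by default the first
    frame's box.  ``align_selection``, when given, least-squares superposes
    every frame onto the first frame on that selection before binning
    (needed only when the structure is free to drift).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = (
        np.flatnonzero(traj.topology.species == species)
        if species in SPECIES_TAGS
        else select(traj, species)
    )
    spacing3 = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if bounds is None:
        box = traj.frames[0].box
        bounds = ((0.0, box[0]), (0.0, box[1]), (0.0, box[2]))
    origin = np.array([b[0] for b in bounds])
    extent = np.array([b[1] - b[0] for b in bounds])
    shape = np.ceil(extent / spacing3 - 1e-9).astype(int)
    if np.any(shape <= 0):
        raise ValueError("grid has zero volume")

    align_idx = select(traj, align_selection) if align_selection else None
    ref = traj.frames[0].positions[align_idx] if align_idx is not None else None

    counts = np.zeros(shape)
    overflow = 0
    n_frames = 0
    for fr in traj.frames[::stride]:
        pos = fr.positions[idx]
        if ref is not None:
            R, t = _kabsch(fr.positions[align_idx], ref)
            pos = pos @ R.T + t
        ijk = np.floor((pos - origin) / spacing3).astype(int)
        ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
        overflow += int(np.sum(~ok))
        np.add.at(counts, tuple(ijk[ok].T), 1.0)
        n_frames += 1
    return DensityGrid(
        origin=origin, spacing=spacing3, counts=counts,
        n_frames=n_frames, species=species, overflow=overflow,
    )


def write_dx(grid: DensityGrid, path: str | Path, what: str = "density") -> None:
    """Write the grid (density by default, or raw counts) as OpenDX."""
    from gridData import Grid

    data = grid.density if what == "density" else grid.counts
    g = Grid(data, origin=grid.origin, delta=grid.spacing)
    g.export(str(path), file_format="dx")


def read_dx(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an OpenDX scalar field; returns (data, origin, spacing)."""
    from gridData import Grid

    g = Grid(str(path))
    return np.asarray(g.grid), np.asarray(g.origin), np.asarray(g.delta)
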