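"""Synthetic inputs with known ground truth for every analysis stage.

Four generators:

* drift–diffusion ion trajectories in a periodic box with an optional
  *planted* number of deterministic full pore crossings — the oracle for
  permeation counting;
* Metropolis samples from harmonically biased analytic 1D free-energy
  surfaces — the oracle for the WHAM solver;
* toy "protein" pores built from rings of atoms whose on-axis maximal
  inscribed sphere radius is known analytically — the oracle for the
  pore-radius profiler;
* hydration shells with water oxygens at exactly prescribed distances — the
  oracle for coordination counting.

Everything is seeded and reproducible; positions are wrapped into the
primary box before they leave this module so the analysis code is always
exercised on wrapped input, as with real MD data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core import Frame, PoreSpec, Topology, Trajectory, wrap_positions
from ._units import kT
from .pmf import UmbrellaWindow

__all__ = [
    "DriftSpec",
    "DriftGroundTruth",
    "PMFSpec",
    "generate_drift_trajectory",
    "sample_umbrella_windows",
    "build_toy_pore",
    "build_hydration_frame",
]


@dataclass(frozen=True)
class DriftSpec:
    """Parameters of the drift–diffusion trajectory generator.

    Ions inside the pore cylinder feel a constant drift ``drift_velocity``
    (Å/ns) along −axis (luminal → cytosolic for ``luminal_side=+1``) on top
    of isotropic diffusion ``diffusion_coefficient`` (Å²/ns); outside the
    cylinder they only diffuse.  ``planted_crossings`` ions instead follow
    deterministic straight-line paths through the pore, giving an exactly
    known crossing count.
    """

    n_ions: int = 10
    n_waters: int = 50
    box: tuple[float, float, float] = (60.0, 60.0, 80.0)
    pore: PoreSpec = field(default_factory=PoreSpec)
    drift_velocity: float = 20.0
    diffusion_coefficient: float = 100.0
    n_frames: int = 100
    dt: float = 0.1
    seed: int = 0
    planted_crossings: int | None = None
    #: static protein-tagged marker atoms ringing the pore centre, so
    #: PoreSpec.center_selection has a physical anchor (as in real systems)
    n_anchor: int = 8

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if self.planted_crossings is not None and self.planted_crossings > self.n_ions:
            raise ValueError("planted_crossings cannot exceed n_ions")
        ax = np.asarray(self.pore.axis, dtype=float)
        if not np.allclose(np.abs(ax), [0, 0, 1]):
            raise ValueError("the drift generator supports a z-aligned pore axis")
        span = abs(self.pore.z_sf - self.pore.z_gate)
        if self.box[2] < span + 24:
            raise ValueError("box z length too small for the pore span plus bulk margins")


@dataclass
class DriftGroundTruth:
    """Exactly known crossing record for a generated trajectory."""

    n_crossings: int
    crosser_indices: list[int]
    crossing_frames: list[int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def generate_drift_trajectory(spec: DriftSpec) -> tuple[Trajectory, DriftGroundTruth]:
    """Overdamped Langevin (Euler–Maruyama) ion dynamics with planted crossers.

    Free ions update as ``x += v·dt·1[in pore] + N(0, 2·D·dt)`` per axis and
    are placed radially outside the cylinder at t=0 so that with D=0 the
    planted count is exactly the total crossing count.  Planted crossers run
    a straight line from the luminal bulk (beyond z_sf) on the axis through
    the cylinder to past z_gate on the cytosolic side, staggered in time.
    """
    rng = np.random.default_rng(spec.seed)
    pore = spec.pore
    box = np.asarray(spec.box, dtype=float)
    center = box / 2.0
    n_plant = spec.planted_crossings or 0
    s = pore.luminal_side

    n_atoms = spec.n_ions + spec.n_waters + spec.n_anchor
    # free ions: uniform, but radially clear of the cylinder
    pos0 = rng.uniform(0, 1, size=(n_atoms, 3)) * box
    if spec.n_anchor:
        ang = 2 * np.pi * np.arange(spec.n_anchor) / spec.n_anchor
        ring_r = pore.cylinder_radius + 4.0
        pos0[-spec.n_anchor :] = np.column_stack([
            center[0] + ring_r * np.cos(ang),
            center[1] + ring_r * np.sin(ang),
            np.full(spec.n_anchor, center[2]),
        ])
    if spec.diffusion_coefficient == 0:
        # deterministic runs: free ions start radially clear of the cylinder
        # so the planted count is exactly the total crossing count
        for i in range(n_plant, spec.n_ions):
            while True:
                xy = rng.uniform(0, 1, size=2) * box[:2]
                if np.linalg.norm(xy - center[:2]) > pore.cylinder_radius + 3.0:
                    break
            pos0[i, :2] = xy

    total_t = (spec.n_frames - 1) * spec.dt
    z_top = center[2] + s * (max(s * pore.z_sf, s * pore.z_gate) + 6.0)
    z_bot = center[2] + s * (min(s * pore.z_sf, s * pore.z_gate) - 6.0)
    # stagger planted crossers across the run; each takes ~60% of the run
    cross_frames: list[int] = []
    plant_paths = np.zeros((n_plant, spec.n_frames))
    for j in range(n_plant):
        f0 = int(round(j * 0.3 * spec.n_frames / max(n_plant, 1)))
        f1 = min(spec.n_frames - 1, f0 + max(2, int(0.6 * spec.n_frames)))
        path = np.full(spec.n_frames, z_top)
        ramp = np.linspace(z_top, z_bot, f1 - f0 + 1)
        path[f0 : f1 + 1] = ramp
        path[f1 + 1 :] = z_bot
        plant_paths[j] = path
        # frame where the path first passes the gate plane
        gate_abs = center[2] + pore.z_gate
        past = np.flatnonzero(s * path < s * gate_abs)
        cross_frames.append(int(past[0]) if past.size else spec.n_frames - 1)

    frames: list[Frame] = []
    pos = pos0.copy()
    sigma = np.sqrt(2.0 * spec.diffusion_coefficient * spec.dt)
    drift = -s * spec.drift_velocity * spec.dt  # luminal→cytosolic along axis
    for fi in range(spec.n_frames):
        snap = pos.copy()
        for j in range(n_plant):
            snap[j] = [center[0], center[1], plant_paths[j, fi]]
        frames.append(
            Frame(time=fi * spec.dt, positions=wrap_positions(snap, box), box=box)
        )
        if fi == spec.n_frames - 1:
            break
        # advance free atoms (the anchor ring stays put)
        if sigma > 0:
            n_free = n_atoms - spec.n_anchor
            pos[:n_free] += rng.normal(0.0, sigma, size=(n_free, 3))
        # drift acts on the whole cylinder column (the field is applied
        # across the membrane, so ions above the mouth are funnelled in)
        rel = wrap_positions(pos, box) - center
        in_col = np.linalg.norm(rel[:, :2], axis=1) <= pore.cylinder_radius
        pos[: spec.n_ions, 2] += drift * in_col[: spec.n_ions]

    na, nw, nc = spec.n_ions, spec.n_waters, spec.n_anchor
    top = Topology(
        names=np.array(["NA"] * na + ["OW"] * nw + ["CA"] * nc),
        elements=np.array(["NA"] * na + ["O"] * nw + ["C"] * nc),
        resnames=np.array(["SOD"] * na + ["SOL"] * nw + ["ALA"] * nc),
        resids=np.arange(1, n_atoms + 1),
        chains=np.array(["I"] * na + ["W"] * nw + ["P"] * nc),
        species=np.array(["cation"] * na + ["water-oxygen"] * nw
                         + ["protein"] * nc),
    )
    truth = DriftGroundTruth(
        n_crossings=n_plant,
        crosser_indices=list(range(n_plant)),
        crossing_frames=cross_frames,
    )
    return Trajectory(frames=frames, topology=top, dt=spec.dt), truth


# ---------------------------------------------------------------------------
# analytic free-energy surfaces and umbrella sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PMFSpec:
    """An analytic 1D free-energy surface U(ξ) on a finite domain.

    Forms: ``flat``; ``harmonic`` (params k0, xi0); ``double-well``
    (params a = barrier height kcal/mol, b = half-separation Å, optional
    center); ``tabulated`` (params xi, U arrays, linearly interpolated).
    """

    form: str = "flat"
    domain: tuple[float, float] = (-10.0, 10.0)
    temperature: float = 310.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in {"flat", "harmonic", "double-well", "tabulated"}:
            raise ValueError(f"unknown PMF form {self.form!r}")
        if not self.domain[1] > self.domain[0]:
            raise ValueError("domain must be an increasing interval")
        u = self.energy(np.linspace(*self.domain, 201))
        if not np.all(np.isfinite(u)):
            raise ValueError("PMF must be finite on its domain")

    def energy(self, xi: np.ndarray) -> np.ndarray:
        """U(ξ) in kcal/mol."""
        xi = np.asarray(xi, dtype=float)
        if self.form == "flat":
            return np.zeros_like(xi)
        if self.form == "harmonic":
            k0 = self.params.get("k0", 1.0)
            xi0 = self.params.get("xi0", 0.0)
            return 0.5 * k0 * (xi - xi0) ** 2
        if self.form == "double-well":
            a = self.params.get("a", 8.0)
            b = self.params.get("b", 5.0)
            c = self.params.get("center", 0.5 * sum(self.domain))
            return a * (((xi - c) / b) ** 2 - 1.0) ** 2
        tab_xi = np.asarray(self.params["xi"], dtype=float)
        tab_u = np.asarray(self.params["U"], dtype=float)
        return np.interp(xi, tab_xi, tab_u)


def _metropolis(
    energy: Callable[[np.ndarray], np.ndarray],
    domain: tuple[float, float],
    kBT: float,
    n_samples: int,
    rng: np.random.Generator,
    n_walkers: int = 64,
    burn_in: int = 500,
    thin: int = 5,
) -> np.ndarray:
    """Vectorised random-walk Metropolis with hard domain walls.

    Walkers start near the minimum of the target energy; the proposal step
    is tuned toward 30–50% acceptance during burn-in (capped at the domain
    width), then frozen for production.
    """
    lo, hi = domain
    grid = np.linspace(lo, hi, 512)
    u = energy(grid)
    x0 = grid[np.argmin(u)]
    n_walkers = min(n_walkers, max(1, n_samples))
    x = np.full(n_walkers, x0) + rng.normal(0, 0.05, n_walkers)
    x = np.clip(x, lo, hi)
    ux = energy(x)
    step = 0.5
    acc_window: list[float] = []
    per_walker = int(np.ceil(n_samples / n_walkers))
    collected = np.empty((per_walker, n_walkers))
    kept = 0
    total_steps = burn_in + per_walker * thin
    for t in range(total_steps):
        prop = x + rng.normal(0, step, n_walkers)
        inside = (prop >= lo) & (prop <= hi)
        u_prop = np.where(inside, energy(np.clip(prop, lo, hi)), np.inf)
        with np.errstate(over="ignore"):
            accept = rng.uniform(size=n_walkers) < np.exp(-(u_prop - ux) / kBT)
        accept &= inside
        x = np.where(accept, prop, x)
        ux = np.where(accept, u_prop, ux)
        if t < burn_in:
            acc_window.append(accept.mean())
            if (t + 1) % 25 == 0:
                rate = float(np.mean(acc_window[-25:]))
                if rate > 0.5:
                    step = min(step * 1.25, hi - lo)
                elif rate < 0.3:
                    step *= 0.8
        elif (t - burn_in + 1) % thin == 0 and kept < per_walker:
            collected[kept] = x
            kept += 1
    return collected.ravel(order="C")[:n_samples]


def sample_umbrella_windows(
    pmf: PMFSpec,
    centers: Sequence[float],
    k: float | Sequence[float],
    n_samples: int = 5000,
    seed: int = 0,
    burn_in: int = 500,
    thin: int = 5,
) -> list[UmbrellaWindow]:
    """Draw seeded Metropolis samples from each biased density
    ∝ exp(−[U(ξ) + ½k(ξ−ξ0)²]/k_BT).

    ``k`` is in kcal mol⁻¹ Å⁻² and may be per-window.  Window seeds are
    spawned from ``seed`` so windows are independent but reproducible.
    """
    centers = list(centers)
    if not centers:
        raise ValueError("centers must be non-empty")
    ks = np.broadcast_to(np.asarray(k, dtype=float), (len(centers),))
    kBT = kT(pmf.temperature)
    seeds = np.random.SeedSequence(seed).spawn(len(centers))
    windows = []
    for (c, ki, ss) in zip(centers, ks, seeds):
        def biased(xi, _c=c, _k=ki):
            return pmf.energy(xi) + 0.5 * _k * (xi - _c) ** 2

        samples = _metropolis(
            biased, pmf.domain, kBT, n_samples,
            np.random.default_rng(ss), burn_in=burn_in, thin=thin,
        )
        windows.append(UmbrellaWindow(center=float(c), k=float(ki), samples=samples))
    return windows


# ---------------------------------------------------------------------------
# toy pores
# ---------------------------------------------------------------------------

def build_toy_pore(
    radius_profile: Callable[[float], float],
    atom_radius: float = 1.5,
    n_per_ring: int = 24,
    z_range: tuple[float, float] = (-10.0, 10.0),
    spacing: float = 0.5,
) -> tuple[Trajectory, dict]:
    """Rings of atoms whose on-axis maximal inscribed sphere radius is known.

    At each level z the ring sits at radius R(z) + atom_radius, so a probe
    sphere on the axis clears the ring atoms by exactly R(z).  The returned
    ground truth includes the exact on-axis inscribed radius accounting for
    neighbouring rings,

        R*(z) = min_i sqrt((R(z_i)+r)² + (z−z_i)²) − r,

    which matters near steep profile changes.  Requires n_per_ring ≥ 6 and
    spacing ≤ atom_radius so no larger sphere can slip between atoms.
    """
    if n_per_ring < 6:
        raise ValueError("n_per_ring must be at least 6")
    if spacing > atom_radius:
        raise ValueError("ring spacing must not exceed atom_radius")
    z_levels = np.arange(z_range[0], z_range[1] + 0.5 * spacing, spacing)
    radii = np.array([float(radius_profile(z)) for z in z_levels])
    if np.any(radii <= 0):
        bad = z_levels[np.argmax(radii <= 0)]
        raise ValueError(f"radius profile must be positive everywhere (R({bad:.2f}) <= 0)")

    max_extent = float((radii + atom_radius).max())
    L_xy = 2 * max_extent + 30.0
    L_z = (z_range[1] - z_range[0]) + 30.0
    box = np.array([L_xy, L_xy, L_z])
    center = box / 2.0
    z_offset = center[2] - 0.5 * (z_range[0] + z_range[1])

    positions = []
    for li, (z, R) in enumerate(zip(z_levels, radii)):
        phase = (li % 2) * np.pi / n_per_ring  # stagger alternate rings
        ang = phase + 2 * np.pi * np.arange(n_per_ring) / n_per_ring
        ring_r = R + atom_radius
        xs = center[0] + ring_r * np.cos(ang)
        ys = center[1] + ring_r * np.sin(ang)
        zs = np.full(n_per_ring, z + z_offset)
        positions.append(np.column_stack([xs, ys, zs]))
    pos = np.concatenate(positions)
    n = len(pos)

    top = Topology(
        names=np.array(["X"] * n),
        elements=np.array(["X"] * n),
        resnames=np.array(["TOY"] * n),
        resids=np.repeat(np.arange(1, len(z_levels) + 1), n_per_ring),
        chains=np.array(["P"] * n),
        species=np.array(["other"] * n),
    )
    traj = Trajectory([Frame(time=0.0, positions=pos, box=box)], top, dt=1.0)

    def analytic_radius(z: np.ndarray | float) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        dz = z[:, None] - z_levels[None, :]
        r_star = np.sqrt((radii + atom_radius) ** 2 + dz**2) - atom_radius
        return r_star.min(axis=1)

    truth = {
        "z_levels": z_levels,
        "requested_radius": radii,
        "analytic_radius": analytic_radius,
        "atom_radius": atom_radius,
        "axis_xy": (center[0], center[1]),
        "z_offset": z_offset,
        "vdw_table": {"X": atom_radius},
        "min_z": float(z_levels[np.argmin(radii)]),
    }
    return traj, truth


# ---------------------------------------------------------------------------
# hydration shells
# ---------------------------------------------------------------------------

def build_hydration_frame(
    ion_position: Sequence[float] = (20.0, 20.0, 20.0),
    water_distances: Sequence[float] = (3.0, 3.0, 3.0, 3.0, 3.0),
    seed: int = 0,
    box: Sequence[float] = (40.0, 40.0, 40.0),
    min_separation: float = 2.0,
) -> Trajectory:
    """One frame: an ion with water oxygens at exactly prescribed distances.

    Directions are drawn uniformly on the sphere (seeded) under the
    constraint that no two waters come closer than ``min_separation``; the
    distance multiset is therefore exact by construction and reproducible.
    """
    rng = np.random.default_rng(seed)
    ion = np.asarray(ion_position, dtype=float)
    box = np.asarray(box, dtype=float)
    placed: list[np.ndarray] = []
    for d in water_distances:
        for _ in range(10_000):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cand = ion + d * v
            if all(np.linalg.norm(cand - p) >= min_separation for p in placed):
                placed.append(cand)
                break
        else:
            raise RuntimeError("could not place waters with the required separation")
    pos = np.vstack([ion] + placed)
    n_w = len(placed)
    top = Topology(
        names=np.array(["NA"] + ["OW"] * n_w),
        elements=np.array(["NA"] + ["O"] * n_w),
        resnames=np.array(["SOD"] + ["SOL"] * n_w),
        resids=np.arange(1, n_w + 2),
        chains=np.array(["I"] + ["W"] * n_w),
        species=np.array(["cation"] + ["water-oxygen"] * n_w),
    )
    frame = Frame(time=0.0, positions=wrap_positions(pos, box), box=box)
    return Trajectory([frame], top, dt=1.0)
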