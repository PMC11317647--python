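"""Potentials of mean force from umbrella sampling via WHAM.

Reconstructs a 1D free-energy profile W(ξ) from harmonically biased windows
using the weighted histogram analysis method: the unbiased bin probabilities

    p(ξ_k) = Σ_i n_i(k) / Σ_i N_i exp[(f_i − u_i(ξ_k)) / k_B T]

and the window free energies

    f_i = −k_B T ln Σ_k p(ξ_k) exp(−u_i(ξ_k) / k_B T)

are iterated to self-consistency from f_i = 0, with convergence measured as
the maximum change in any f_i between sweeps.  W(ξ) = −k_B T ln p(ξ) is
shifted so its global minimum is zero.  Statistical uncertainty comes from a
window-wise bootstrap: each window's samples are resampled with replacement,
WHAM is re-run per replicate, and per-bin standard deviations are taken after
re-zeroing every replicate.

Force constants are stored in kcal mol⁻¹ Å⁻²; values supplied in the common
biased-MD convention of kJ mol⁻¹ nm⁻² are converted at ingest
(1000 kJ mol⁻¹ nm⁻² = 2.390 kcal mol⁻¹ Å⁻²).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._units import kT, kj_nm2_to_kcal_A2

logger = logging.getLogger(__name__)

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "wham",
    "bootstrap_errors",
    "observable_vs_xi",
    "load_window_file",
    "load_manifest",
]


@dataclass
class UmbrellaWindow:
    """One umbrella window: bias centre ξ0 (Å), force constant k
    (kcal mol⁻¹ Å⁻²), and the reaction-coordinate samples ξ_t (Å) retained
    after discarding equilibration."""

    center: float
    k: float
    samples: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.k < 0:
            raise ValueError("force constant must be >= 0")
        if self.samples.size == 0:
            raise ValueError("window has no samples after equilibration cut")

    def bias(self, xi: np.ndarray) -> np.ndarray:
        """Harmonic bias energy u(ξ) = ½ k (ξ − ξ0)² in kcal/mol."""
        return 0.5 * self.k * (np.asarray(xi) - self.center) ** 2


@dataclass
class PMFProfile:
    """Free-energy profile on a ξ grid (bin centres, Å), W in kcal/mol
    (global minimum = 0), optional per-bin bootstrap SD."""

    xi: np.ndarray
    W: np.ndarray
    error: np.ndarray | None = None
    window_free_energies: np.ndarray | None = None
    n_iterations: int = 0

    def barrier(self, xi_range: tuple[float, float] | None = None) -> float:
        """Maximum of W, optionally restricted to a ξ interval, minus the
        global minimum (which is 0 under the min-zero convention)."""
        mask = np.isfinite(self.W)
        if xi_range is not None:
            mask &= (self.xi >= xi_range[0]) & (self.xi <= xi_range[1])
        return float(np.max(self.W[mask]))

    def to_frame(self) -> pd.DataFrame:
        data = {"xi_A": self.xi, "pmf_kcal_mol": self.W}
        if self.error is not None:
            data["bootstrap_sd_kcal_mol"] = self.error
        return pd.DataFrame(data)


def _histograms(
    windows: list[UmbrellaWindow], bin_width: float, grid: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin every window's samples on a common grid; returns (centers, n_ik, edges)."""
    if grid is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
        edges = lo + bin_width * np.arange(n_bins + 1)
    else:
        edges = np.asarray(grid, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_ik = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    return centers, n_ik.astype(float), edges


def _check_overlap(windows: list[UmbrellaWindow], n_ik: np.ndarray,
                   centers: np.ndarray) -> None:
    # chain connectivity: the union of window sample ranges must be one
    # interval (isolated sparse bins inside the coverage are fine, they just
    # come out as NaN in W)
    ivals = sorted((w.samples.min(), w.samples.max()) for w in windows)
    reach = ivals[0][1]
    for lo, hi in ivals[1:]:
        if lo > reach:
            raise ValueError(
                f"umbrella windows do not overlap: no samples in ξ ∈ "
                f"[{reach:.2f}, {lo:.2f}] Å — the window chain is broken"
            )
        reach = max(reach, hi)
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((n_ik[a] > 0) & (n_ik[b] > 0)):
            warnings.warn(
                f"adjacent windows at ξ0={windows[a].center:.2f} and "
                f"{windows[b].center:.2f} Å share no histogram bin",
                stacklevel=3,
            )


def wham(
    windows: list[UmbrellaWindow],
    bin: float = 0.2,
    temperature: float = 310.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    grid: np.ndarray | None = None,
    f_init: np.ndarray | None = None,
    check_overlap: bool = True,
) -> PMFProfile:
    """Self-consistent WHAM solve.

    Parameters
    ----------
    windows : biased windows with samples in Å and k in kcal mol⁻¹ Å⁻².
    bin : histogram bin width (Å); ignored when an explicit ``grid`` of bin
        edges is supplied (bootstrap replicates reuse the full-data grid).
    temperature : K.
    tol : convergence threshold on max |Δf_i| (kcal/mol).
    f_init : optional warm start for the window free energies.

    Raises
    ------
    ValueError : empty window list or a broken (non-overlapping) chain.
    RuntimeError : no convergence within ``max_iter`` (reports the residual).
    """
    if not windows:
        raise ValueError("wham requires at least one window")
    kBT = kT(temperature)
    centers, n_ik, edges = _histograms(windows, bin, grid)
    if check_overlap and len(windows) > 1:
        _check_overlap(windows, n_ik, centers)

    N_i = n_ik.sum(axis=1)  # samples per window
    n_k = n_ik.sum(axis=0)  # total per bin
    u_ik = np.stack([w.bias(centers) for w in windows])  # (n_win, n_bin)
    with np.errstate(under="ignore"):
        boltz = np.exp(-u_ik / kBT)

    f = np.zeros(len(windows)) if f_init is None else np.array(f_init, dtype=float)
    occupied = n_k > 0
    residual = np.inf
    for it in range(1, max_iter + 1):
        with np.errstate(under="ignore", divide="ignore", invalid="ignore"):
            denom = (N_i[:, None] * np.exp(f[:, None] / kBT) * boltz).sum(axis=0)
            p = np.where(occupied, n_k / denom, 0.0)
            z_i = boltz @ p
            f_new = -kBT * np.log(z_i)
        f_new -= f_new[0]  # gauge fix
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} kcal/mol > tol {tol:g})"
        )

    with np.errstate(divide="ignore"):
        W = np.where(occupied, -kBT * np.log(p), np.nan)
    W -= np.nanmin(W)
    return PMFProfile(
        xi=centers, W=W, window_free_energies=f, n_iterations=it
    )


def bootstrap_errors(
    windows: list[UmbrellaWindow],
    n_boot: int = 100,
    seed: int = 0,
    bin: float = 0.2,
    temperature: float = 310.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> PMFProfile:
    """Window-wise bootstrap of the WHAM profile.

    Each replicate resamples every window's ξ samples i.i.d. with
    replacement, re-runs WHAM on the full-data bin grid (warm-started from
    the full-data solution), re-zeroes the replicate to its own minimum, and
    the per-bin SD over replicates becomes the error band.  Seeded and
    reproducible.
    """
    base_centers, _, edges = _histograms(windows, bin, None)
    full = wham(windows, bin=bin, temperature=temperature, tol=tol,
                max_iter=max_iter, grid=edges)
    rng = np.random.default_rng(seed)
    reps = np.full((n_boot, len(base_centers)), np.nan)
    for b in range(n_boot):
        resampled = [
            UmbrellaWindow(
                center=w.center,
                k=w.k,
                samples=rng.choice(w.samples, size=w.samples.size, replace=True),
            )
            for w in windows
        ]
        prof = wham(
            resampled, grid=edges, temperature=temperature, tol=tol,
            max_iter=max_iter, f_init=full.window_free_energies,
            check_overlap=False,
        )
        reps[b] = prof.W
    if n_boot > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            sd = np.nanstd(reps, axis=0, ddof=0)
    else:
        sd = np.zeros(len(base_centers))
    return PMFProfile(
        xi=full.xi, W=full.W, error=sd,
        window_free_energies=full.window_free_energies,
        n_iterations=full.n_iterations,
    )


def observable_vs_xi(
    windows: list[UmbrellaWindow],
    observables: list[np.ndarray],
    statistic: str = "mean",
    mode: str = "per-window",
    bin: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Profile of a per-sample observable along the reaction coordinate.

    ``per-window`` mode reports the window statistic at each ξ0 (how
    hydration-vs-ξ curves are usually assembled); ``binned`` mode pools all
    samples and bins them by their sampled ξ.  The two agree for narrow
    windows.
    """
    stat_fn = {"mean": np.mean, "median": np.median, "min": np.min}[statistic]
    obs = [np.asarray(o, dtype=float) for o in observables]
    for w, o in zip(windows, obs):
        if o.shape != w.samples.shape:
            raise ValueError("observable series must match window samples in length")
    if mode == "per-window":
        order = np.argsort([w.center for w in windows])
        xi = np.array([windows[i].center for i in order])
        vals = np.array([stat_fn(obs[i]) for i in order])
        return xi, vals
    if mode == "binned":
        all_xi = np.concatenate([w.samples for w in windows])
        all_obs = np.concatenate(obs)
        lo, hi = all_xi.min(), all_xi.max()
        edges = np.arange(lo, hi + bin, bin)
        idx = np.clip(np.digitize(all_xi, edges) - 1, 0, len(edges) - 2)
        centers = 0.5 * (edges[:-1] + edges[1:])
        vals = np.full(len(centers), np.nan)
        for k in range(len(centers)):
            sel = idx == k
            if sel.any():
                vals[k] = stat_fn(all_obs[sel])
        keep = np.isfinite(vals)
        return centers[keep], vals[keep]
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# window file I/O
# ---------------------------------------------------------------------------

def load_window_file(
    path: str | Path,
    center: float,
    k: float,
    equilibration_cut: float = 2.0,
    k_units: str = "kcal/mol/A2",
) -> UmbrellaWindow:
    """Read one plain-text window file with columns (time [ns], ξ [Å]).

    Samples with time < ``equilibration_cut`` (ns; default 2) are discarded.
    ``k_units`` may be ``kcal/mol/A2`` or ``kJ/mol/nm2`` (converted on
    ingest).
    """
    data = np.loadtxt(path, comments=("#", "@"))
    if data.ndim == 1:
        data = data.reshape(1, -1)
    t, xi = data[:, 0], data[:, 1]
    keep = t >= equilibration_cut
    if k_units == "kJ/mol/nm2":
        k = kj_nm2_to_kcal_A2(k)
    elif k_units != "kcal/mol/A2":
        raise ValueError(f"unknown force-constant units {k_units!r}")
    return UmbrellaWindow(
        center=center, k=k, samples=xi[keep],
        source={"path": str(path), "equilibration_cut_ns": equilibration_cut},
    )


def load_manifest(path: str | Path) -> list[UmbrellaWindow]:
    """Load windows from a JSON or CSV manifest.

    Each record needs ``path``, ``center`` (Å), ``k``, and optionally
    ``equilibration_cut`` (ns) and ``k_units``.  Relative window paths are
    resolved against the manifest's directory.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    windows = []
    for rec in records:
        wpath = Path(rec["path"])
        if not wpath.is_absolute():
            wpath = path.parent / wpath
        windows.append(
            load_window_file(
                wpath,
                center=float(rec["center"]),
                k=float(rec["k"]),
                equilibration_cut=float(rec.get("equilibration_cut", 2.0)),
                k_units=str(rec.get("k_units", "kcal/mol/A2")),
            )
        )
    return windows
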