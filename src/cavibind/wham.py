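"""Weighted histogram analysis method (WHAM) for umbrella-sampled PMFs.

Binned, Kumar-style self-consistent WHAM.  Each window ``i`` contributes a
histogram ``n_ib`` over a common grid of z-bins; the unbiased probability and
the per-window free-energy shifts are iterated to self-consistency:

    p_b  = (sum_i n_ib) / (sum_i N_i exp(f_i/RT) c_ib),
    exp(-f_i/RT) = sum_b c_ib p_b,

with ``c_ib = exp(-u_i(z_b)/RT)`` the Boltzmann factor of window i's z-bias at
the bin centre.  Only the z-umbrella enters the bias list: the flat-bottom xy
cylinder is common to every window and is part of the (restrained) system, so
it is handled downstream by the standard-state cylinder correction, not by
WHAM.

The PMF is W(z) = -RT ln p(z), referenced so the declared bulk region averages
to zero.  Empty bins are masked (NaN), never interpolated.  Uncertainties come
from contiguous-in-time blocks: the per-window data are split into equal-
duration blocks, WHAM is repeated per block, and the per-bin standard
deviation across blocks is the error bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .geometry import RestraintSpec

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "wham",
    "histogram_overlap",
    "block_pmfs",
    "set_reference",
]


@dataclass
class UmbrellaWindow:
    """One biased window: restraint plus sampled reaction-coordinate series."""

    restraint: Optional[RestraintSpec]
    times: np.ndarray
    z: np.ndarray
    x: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.size < 1:
            raise ValueError("window must contain at least one sample")
        if self.times.size != self.z.size:
            raise ValueError("times and z must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("x", "y"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.z.size

    def slice_time(self, t_lo: float, t_hi: float) -> "UmbrellaWindow":
        """Samples with t_lo <= t < t_hi (no revalidation of emptiness)."""
        m = (self.times >= t_lo) & (self.times < t_hi)
        if not np.any(m):
            raise ValueError(f"window {self.label!r}: no samples in [{t_lo}, {t_hi}) ps")
        return UmbrellaWindow(
            restraint=self.restraint,
            times=self.times[m],
            z=self.z[m],
            x=None if self.x is None else self.x[m],
            y=None if self.y is None else self.y[m],
            label=self.label,
        )


@dataclass
class PMFProfile:
    """Free-energy profile W(z) on a uniform grid with per-bin uncertainty.

    ``W`` is NaN on unoccupied bins; ``reference_region`` is the (z_lo, z_hi)
    interval whose occupied bins average to zero.
    """

    z_grid: np.ndarray
    W: np.ndarray
    W_sd: Optional[np.ndarray]
    reference_region: Tuple[float, float]
    occupied_mask: np.ndarray
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.occupied_mask = np.asarray(self.occupied_mask, dtype=bool)
        if self.counts is None:
            self.counts = np.zeros_like(self.z_grid)

    @property
    def bin_width(self) -> float:
        return float(self.z_grid[1] - self.z_grid[0]) if self.z_grid.size > 1 else 0.0

    def is_referenced(self, atol: float = 1e-8) -> bool:
        lo, hi = self.reference_region
        m = self.occupied_mask & (self.z_grid >= lo) & (self.z_grid <= hi)
        if not np.any(m):
            return False
        return abs(float(np.mean(self.W[m]))) < atol

    def minimum(self) -> Tuple[float, float]:
        """(W_min, z_min) over occupied bins; ties broken toward smaller |z|."""
        if not np.any(self.occupied_mask):
            raise ValueError("profile has no occupied bins")
        w = np.where(self.occupied_mask, self.W, np.inf)
        wmin = float(np.min(w))
        tie = np.isclose(w, wmin, rtol=0.0, atol=1e-12)
        zc = self.z_grid[tie]
        order = np.lexsort((zc, np.abs(zc)))
        return wmin, float(zc[order[0]])


def _bin_edges(z_values: np.ndarray, bin_width: float) -> np.ndarray:
    lo = math.floor(np.min(z_values) / bin_width)
    hi = math.ceil(np.max(z_values) / bin_width)
    if hi <= lo:
        hi = lo + 1
    return bin_width * np.arange(lo, hi + 1)


def _default_reference(
    z_grid: np.ndarray,
    occupied: np.ndarray,
    windows: Optional[Sequence[UmbrellaWindow]] = None,
) -> Tuple[float, float]:
    """Outermost 2 A of the sampled range, kept inside the umbrella coverage.

    The occupied range extends past the last umbrella centre into the thinly
    populated tail of its histogram; referencing there would add a large
    common-mode offset to the whole profile.  When restraints are known the
    bulk region therefore ends at the outermost umbrella centre.
    """
    z_occ = z_grid[occupied]
    hi = float(z_occ.max())
    if windows is not None:
        centers = [w.restraint.z_center for w in windows if w.restraint is not None]
        if centers:
            c_max = max(centers)
            m = occupied & (z_grid >= c_max - 2.0) & (z_grid <= c_max)
            if np.any(m):
                return float(c_max - 2.0), float(c_max)
    return hi - 2.0, hi


def _check_connectivity(counts: np.ndarray, labels: Sequence[str]) -> None:
    """Error out if the occupied bins of the windows form disconnected clusters."""
    n_win = counts.shape[0]
    occ = counts > 0
    parent = list(range(n_win))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n_win):
        for j in range(i + 1, n_win):
            if np.any(occ[i] & occ[j]):
                parent[find(i)] = find(j)
    groups: dict = {}
    for i in range(n_win):
        groups.setdefault(find(i), []).append(labels[i] or f"window {i}")
    if len(groups) > 1:
        desc = "; ".join("{" + ", ".join(g) + "}" for g in groups.values())
        raise ValueError(f"windows form {len(groups)} disconnected overlap clusters: {desc}")


def _wham_core(
    counts: np.ndarray,
    c_ib: np.ndarray,
    rt: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Self-consistent iteration; returns unnormalised bin probabilities.

    ``counts``: (n_windows, n_bins) histograms; ``c_ib``: bias Boltzmann
    factors at bin centres.  Convergence is on the window free energies f_i in
    kcal/mol.
    """
    n_i = counts.sum(axis=1).astype(float)
    h_b = counts.sum(axis=0).astype(float)
    f = np.zeros(counts.shape[0])
    occupied = h_b > 0
    for _ in range(max_iter):
        g = np.exp(f / rt)
        denom = (n_i * g) @ c_ib
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied & (denom > 0), h_b / denom, 0.0)
        p_sum = p.sum()
        if p_sum <= 0:
            raise ValueError("WHAM produced an empty distribution")
        p /= p_sum
        s = c_ib @ p
        f_new = np.where(s > 0, -rt * np.log(np.maximum(s, 1e-300)), f)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol:
            return p
    raise RuntimeError(
        f"WHAM did not converge in {max_iter} iterations (final residual {resid:.3e} kcal/mol)"
    )


def wham(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = 0.1,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    temperature: float = DEFAULT_TEMPERATURE,
    bin_edges: Optional[np.ndarray] = None,
    reference_region: Optional[Tuple[float, float]] = None,
) -> PMFProfile:
    """Estimate the PMF from umbrella windows.

    Parameters follow the module defaults: 0.1 A bins, tolerance 1e-7 kcal/mol
    on the window shifts, at most 1e5 iterations.  ``bin_edges`` overrides the
    automatic grid (used by block averaging to keep grids aligned).
    """
    if len(windows) == 0:
        raise ValueError("at least one window is required")
    rt = thermal_energy(temperature)
    if bin_edges is None:
        all_z = np.concatenate([w.z for w in windows])
        bin_edges = _bin_edges(all_z, bin_width)
    bin_edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])

    counts = np.stack([np.histogram(w.z, bins=bin_edges)[0] for w in windows])
    _check_connectivity(counts, [w.label for w in windows])

    u = np.zeros((len(windows), centers.size))
    for i, w in enumerate(windows):
        if w.restraint is not None:
            u[i] = 0.5 * w.restraint.k_z * (centers - w.restraint.z_center) ** 2
    c_ib = np.exp(-u / rt)

    p = _wham_core(counts, c_ib, rt, tol, max_iter)
    occupied = counts.sum(axis=0) > 0
    W = np.full(centers.size, np.nan)
    W[occupied] = -rt * np.log(p[occupied])

    profile = PMFProfile(
        z_grid=centers,
        W=W,
        W_sd=None,
        reference_region=reference_region or _default_reference(centers, occupied, windows),
        occupied_mask=occupied,
        counts=counts.sum(axis=0).astype(float),
    )
    return set_reference(profile, profile.reference_region)


def set_reference(profile: PMFProfile, region: Tuple[float, float]) -> PMFProfile:
    """Shift W so its occupied-bin mean over ``region`` is zero (idempotent)."""
    lo, hi = region
    m = profile.occupied_mask & (profile.z_grid >= lo) & (profile.z_grid <= hi)
    if not np.any(m):
        raise ValueError(f"reference region [{lo}, {hi}] contains no occupied bins")
    shift = float(np.mean(profile.W[m]))
    return replace(profile, W=profile.W - shift, reference_region=(float(lo), float(hi)))


def histogram_overlap(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = 0.1,
    threshold: float = 0.03,
) -> pd.DataFrame:
    """Overlap coefficient sum_b min(p1_b, p2_b) for each adjacent window pair.

    Windows are ordered by umbrella centre; pairs with overlap below
    ``threshold`` are flagged as potential gaps in the sampling.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows to compute overlap")
    order = sorted(
        range(len(windows)),
        key=lambda i: windows[i].restraint.z_center if windows[i].restraint else 0.0,
    )
    edges = _bin_edges(np.concatenate([w.z for w in windows]), bin_width)
    hists = [np.histogram(windows[i].z, bins=edges)[0] for i in order]
    rows = []
    for a, b in zip(range(len(order) - 1), range(1, len(order))):
        p1 = hists[a] / hists[a].sum()
        p2 = hists[b] / hists[b].sum()
        ovl = float(np.minimum(p1, p2).sum())
        w1, w2 = windows[order[a]], windows[order[b]]
        rows.append(
            {
                "label_1": w1.label,
                "label_2": w2.label,
                "center_1": w1.restraint.z_center if w1.restraint else np.nan,
                "center_2": w2.restraint.z_center if w2.restraint else np.nan,
                "overlap": ovl,
                "flagged": ovl < threshold,
            }
        )
    return pd.DataFrame(rows)


def block_pmfs(
    windows: Sequence[UmbrellaWindow],
    n_blocks: int = 3,
    equil_discard: float = 0.0,
    bin_width: float = 0.1,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    temperature: float = DEFAULT_TEMPERATURE,
    reference_region: Optional[Tuple[float, float]] = None,
) -> Tuple[PMFProfile, List[PMFProfile]]:
    """Block-averaged PMF with per-bin scatter across contiguous time blocks.

    Each window's first ``equil_discard`` ps are dropped as equilibration; the
    remainder is split into ``n_blocks`` contiguous equal-duration blocks (by
    simulation time, not sample count).  WHAM is run per block on a common bin
    grid, each block profile is referenced to the bulk region, and the mean
    profile carries the per-bin standard deviation across blocks (absent when
    ``n_blocks`` is 1).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    trimmed = []
    for w in windows:
        t0 = w.times[0] + equil_discard
        if w.times[-1] <= t0:
            raise ValueError(f"window {w.label!r}: nothing left after discarding {equil_discard} ps")
        m = w.times >= t0
        trimmed.append(
            UmbrellaWindow(w.restraint, w.times[m], w.z[m],
                           None if w.x is None else w.x[m],
                           None if w.y is None else w.y[m], w.label)
        )

    all_z = np.concatenate([w.z for w in trimmed])
    edges = _bin_edges(all_z, bin_width)
    if reference_region is None:
        centers = 0.5 * (edges[:-1] + edges[1:])
        occ = np.histogram(all_z, bins=edges)[0] > 0
        reference_region = _default_reference(centers, occ, trimmed)

    block_profiles: List[PMFProfile] = []
    for b in range(n_blocks):
        block_windows = []
        for w in trimmed:
            t_start, t_end = w.times[0], w.times[-1]
            span = (t_end - t_start) / n_blocks
            lo = t_start + b * span
            hi = t_start + (b + 1) * span if b < n_blocks - 1 else np.inf
            try:
                block_windows.append(w.slice_time(lo, hi))
            except ValueError as exc:
                raise ValueError(f"empty block {b} in window {w.label!r}") from exc
        block_profiles.append(
            wham(block_windows, bin_width=bin_width, tol=tol, max_iter=max_iter,
                 temperature=temperature, bin_edges=edges,
                 reference_region=reference_region)
        )

    if n_blocks == 1:
        return block_profiles[0], block_profiles

    stack = np.stack([p.W for p in block_profiles])
    occ_all = np.all(np.stack([p.occupied_mask for p in block_profiles]), axis=0)
    mean_w = np.full(stack.shape[1], np.nan)
    sd = np.full(stack.shape[1], np.nan)
    mean_w[occ_all] = stack[:, occ_all].mean(axis=0)
    sd[occ_all] = stack[:, occ_all].std(axis=0, ddof=1)
    counts = np.sum(np.stack([p.counts for p in block_profiles]), axis=0)
    mean_profile = PMFProfile(
        z_grid=block_profiles[0].z_grid,
        W=mean_w,
        W_sd=sd,
        reference_region=reference_region,
        occupied_mask=occ_all,
        counts=counts,
    )
    return set_reference(mean_profile, reference_region), block_profiles
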