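"""Hydration-shell profiles and cavity wetting/de-wetting statistics.

For every frame the number of water oxygens (and optionally host atoms) within
a cutoff of the ion is counted and binned along the reaction coordinate; the
per-bin mean and standard deviation form the hydration profile.  Separately,
the cavity is classified per frame as *wetted* (at least one water within
``cavity_cutoff`` of the cavity centre, default 3 A) or *de-wetted* (none),
and dwell-time statistics of the resulting two-state series are reported.

All distance comparisons use a closed interval (distance <= cutoff), so
boundary cases are deterministic and bit-exact in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import HostGeometry, cavity_center

__all__ = [
    "SolventFrame",
    "HydrationProfile",
    "WettingTrace",
    "count_shell",
    "hydration_profile",
    "classify_wetting",
    "wetting_report",
]

DEFAULT_WATER_CUTOFF = 3.4
DEFAULT_HOST_CUTOFF = 4.0
DEFAULT_CAVITY_CUTOFF = 3.0


@dataclass
class SolventFrame:
    """Coordinates of guest ion, pseudo-waters and host for one time step."""

    time: float
    ion: np.ndarray
    waters: np.ndarray
    host: HostGeometry
    z_dist: float

    def __post_init__(self) -> None:
        self.ion = np.asarray(self.ion, dtype=float)
        self.waters = np.asarray(self.waters, dtype=float).reshape(-1, 3)
        if not (np.all(np.isfinite(self.ion)) and np.all(np.isfinite(self.waters))):
            raise ValueError("non-finite coordinates in solvent frame")
        expected = self.ion[2] - cavity_center(self.host)[2]
        if abs(self.z_dist - expected) > 1e-6:
            raise ValueError(
                f"cached z_dist {self.z_dist} inconsistent with ion/host ({expected})"
            )


@dataclass
class HydrationProfile:
    bin_edges: np.ndarray
    mean_water_count: np.ndarray
    sd_water_count: np.ndarray
    mean_host_contacts: np.ndarray
    sd_host_contacts: np.ndarray
    n_frames: np.ndarray
    water_cutoff: float = DEFAULT_WATER_CUTOFF
    host_cutoff: float = DEFAULT_HOST_CUTOFF

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class WettingTrace:
    """Boolean wetted/de-wetted series with dwell statistics.

    Dwell times of runs touching either end of the trace are censored and
    excluded from the dwell lists, but all frames count toward the fractions.
    """

    times: np.ndarray
    wetted: np.ndarray
    fraction_dewetted: float
    n_transitions: int
    dwell_times: Dict[str, List[float]] = field(default_factory=dict)
    label: str = ""

    @property
    def fraction_wetted(self) -> float:
        return 1.0 - self.fraction_dewetted

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size > 1 else 0.0


def count_shell(
    frame: SolventFrame,
    water_cutoff: float = DEFAULT_WATER_CUTOFF,
    host_cutoff: float = DEFAULT_HOST_CUTOFF,
) -> Tuple[int, int]:
    """Waters and host atoms within the cutoffs of the ion (closed interval)."""
    if water_cutoff <= 0 or host_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    n_w = 0
    if frame.waters.size:
        d = np.linalg.norm(frame.waters - frame.ion, axis=1)
        n_w = int(np.count_nonzero(d <= water_cutoff))
    d_host = np.linalg.norm(frame.host.all_atoms - frame.ion, axis=1)
    n_h = int(np.count_nonzero(d_host <= host_cutoff))
    return n_w, n_h


def hydration_profile(
    frames: Sequence[SolventFrame],
    bin_width: float = 1.0,
    water_cutoff: float = DEFAULT_WATER_CUTOFF,
    host_cutoff: float = DEFAULT_HOST_CUTOFF,
    signed: bool = True,
) -> HydrationProfile:
    """Bin per-frame shell counts along the reaction coordinate.

    ``signed=False`` folds to |z_dist|.  Empty bins are kept with
    ``n_frames = 0``; the per-bin error bar is the population SD of the counts.
    """
    if len(frames) == 0:
        raise ValueError("at least one frame is required")
    z = np.array([f.z_dist for f in frames])
    if not signed:
        z = np.abs(z)
    counts = np.array([count_shell(f, water_cutoff, host_cutoff) for f in frames], dtype=float)

    lo = np.floor(z.min() / bin_width)
    hi = np.ceil(z.max() / bin_width)
    if hi <= lo:
        hi = lo + 1
    edges = bin_width * np.arange(lo, hi + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, len(edges) - 2)

    n_bins = len(edges) - 1
    mean_w = np.full(n_bins, np.nan)
    sd_w = np.full(n_bins, np.nan)
    mean_h = np.full(n_bins, np.nan)
    sd_h = np.full(n_bins, np.nan)
    n_frames = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        m = idx == b
        n_frames[b] = int(np.count_nonzero(m))
        if n_frames[b]:
            mean_w[b] = counts[m, 0].mean()
            sd_w[b] = counts[m, 0].std()
            mean_h[b] = counts[m, 1].mean()
            sd_h[b] = counts[m, 1].std()
    return HydrationProfile(edges, mean_w, sd_w, mean_h, sd_h, n_frames,
                            water_cutoff, host_cutoff)


def classify_wetting(
    frames: Sequence[SolventFrame],
    cavity_cutoff: float = DEFAULT_CAVITY_CUTOFF,
) -> WettingTrace:
    """Two-state wetted/de-wetted classification of the cavity.

    A frame is wetted if any water lies within ``cavity_cutoff`` of the cavity
    centre (centroid of the cavity atoms).  Frames must be time-ordered.
    """
    if len(frames) == 0:
        raise ValueError("at least one frame is required")
    times = np.array([f.time for f in frames])
    if np.any(np.diff(times) <= 0):
        raise ValueError("frames must be strictly time-ordered")
    center = cavity_center(frames[0].host)
    wetted = np.empty(len(frames), dtype=bool)
    for i, f in enumerate(frames):
        if f.waters.size:
            d = np.linalg.norm(f.waters - center, axis=1)
            wetted[i] = bool(np.any(d <= cavity_cutoff))
        else:
            wetted[i] = False

    changes = np.flatnonzero(np.diff(wetted.astype(np.int8)) != 0)
    n_transitions = int(changes.size)
    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.0

    dwell: Dict[str, List[float]] = {"wetted": [], "dewetted": []}
    # run boundaries; first and last runs are censored
    bounds = np.concatenate(([0], changes + 1, [len(frames)]))
    for k in range(1, len(bounds) - 2):
        start, stop = bounds[k], bounds[k + 1]
        state = "wetted" if wetted[start] else "dewetted"
        dwell[state].append((stop - start) * dt)

    return WettingTrace(
        times=times,
        wetted=wetted,
        fraction_dewetted=float(np.mean(~wetted)),
        n_transitions=n_transitions,
        dwell_times=dwell,
    )


def wetting_report(traces: Dict[str, WettingTrace]) -> pd.DataFrame:
    """Per-system summary: de-wetted fraction, transition rate, mean dwells."""
    if len(traces) == 0:
        raise ValueError("at least one trace is required")
    rows = []
    for name, tr in traces.items():
        dur_ns = tr.duration / 1000.0
        rows.append(
            {
                "system": name,
                "fraction_dewetted": tr.fraction_dewetted,
                "n_transitions": tr.n_transitions,
                "transitions_per_ns": tr.n_transitions / dur_ns if dur_ns > 0 else np.nan,
                "mean_dwell_wetted_ps": (
                    float(np.mean(tr.dwell_times["wetted"])) if tr.dwell_times.get("wetted") else np.nan
                ),
                "mean_dwell_dewetted_ps": (
                    float(np.mean(tr.dwell_times["dewetted"])) if tr.dwell_times.get("dewetted") else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
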