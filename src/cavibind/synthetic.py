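"""Synthetic datasets with analytically known ground truth.

This module produces everything the analysis layer consumes, with the
statistical structure the estimators assume:

* biased Brownian-dynamics umbrella windows on a separable model landscape
  (:func:`generate_umbrella_dataset`), whose exact PMF is available from
  :func:`analytic_pmf`;
* idealised host geometries (a ring of cavity atoms, optionally flanked by
  charged/vdW sites);
* pseudo-solvent frames (:func:`generate_solvent_frames`) in which the
  ion's hydration-shell count decays sigmoidally as the ion approaches the
  cavity and the cavity itself wets/de-wets as a two-state Markov process.

All randomness is seeded; per-window seeds are ``master_seed + window_index``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .constants import thermal_energy
from .geometry import HostGeometry, RestraintSpec, cavity_center
from .potential import ModelPotential, default_landscape
from .sampler import BrownianParams, simulate_window
from .solvation import SolventFrame
from .wham import PMFProfile, UmbrellaWindow, set_reference

__all__ = [
    "SolventModel",
    "analytic_pmf",
    "generate_umbrella_dataset",
    "generate_host_geometry",
    "generate_solvent_frames",
    "default_landscape",
    "default_window_specs",
]


@dataclass(frozen=True)
class SolventModel:
    """Parameters of the pseudo-solvent generator.

    ``bulk_count_mean`` waters are expected within ``shell_cutoff`` of the ion
    in bulk; the expectation is scaled by the replacement sigmoid
    ``s(d) = 1/(1+exp(-(d - cavity_radius)/replacement_halfwidth))`` with d the
    ion-cavity distance, emulating partial replacement of the hydration shell
    by host contacts near the cavity.  Cavity occupancy is a two-state Markov
    process with wetting/drying rates ``k_wet``/``k_dry`` (ps^-1); defaults
    give a stationary de-wetted fraction of 12.5% with picosecond dwell times.
    """

    bulk_count_mean: float = 6.0
    replacement_halfwidth: float = 1.0
    k_wet: float = 0.35
    k_dry: float = 0.05
    cavity_radius: float = 3.0
    shell_cutoff: float = 3.4

    def __post_init__(self) -> None:
        if self.bulk_count_mean < 0 or self.k_wet < 0 or self.k_dry < 0:
            raise ValueError("rates and counts must be non-negative")
        if self.replacement_halfwidth <= 0 or self.cavity_radius <= 0 or self.shell_cutoff <= 0:
            raise ValueError("length scales must be positive")

    def replacement_factor(self, d):
        """s(d): fraction of the bulk shell count retained at ion-cavity distance d."""
        d = np.asarray(d, dtype=float)
        return 1.0 / (1.0 + np.exp(-(d - self.cavity_radius) / self.replacement_halfwidth))

    @property
    def stationary_wetted_fraction(self) -> float:
        total = self.k_wet + self.k_dry
        return self.k_wet / total if total > 0 else 1.0


def analytic_pmf(
    model: ModelPotential,
    r_cyl: Optional[float],
    grid: Sequence[float],
    reference_region: Optional[Tuple[float, float]] = None,
) -> PMFProfile:
    """Exact PMF of the model restrained to a cylinder of radius ``r_cyl``.

    W(z) = -RT ln Int_{x^2+y^2<r_cyl^2} exp(-U(x,y,z)/RT) dx dy + C, with C
    fixed so the reference region averages to zero.  For the separable model
    the radial integral has the closed form (2 pi RT / k)(1 - exp(-k r^2/2RT)),
    so W equals U_z up to a constant.  ``r_cyl=None`` means an unbounded
    xy-plane, which requires radial confinement.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    if r_cyl is not None and r_cyl <= 0:
        raise ValueError("r_cyl must be positive")
    rt = thermal_energy(model.temperature)
    k = model.radial_k
    if k > 0:
        if r_cyl is None:
            radial = 2.0 * np.pi * rt / k
        else:
            radial = (2.0 * np.pi * rt / k) * (1.0 - np.exp(-k * r_cyl**2 / (2.0 * rt)))
    else:
        if r_cyl is None:
            raise ValueError(
                "radial_k = 0 with an unbounded xy-plane gives a divergent "
                "configurational integral; set radial_k > 0 or a finite r_cyl"
            )
        radial = np.pi * r_cyl**2
    w = model.u_z(grid) - rt * np.log(radial)
    profile = PMFProfile(
        z_grid=grid,
        W=w,
        W_sd=None,
        reference_region=reference_region or (float(grid.max() - 2.0), float(grid.max())),
        occupied_mask=np.ones(grid.size, dtype=bool),
        counts=np.zeros(grid.size),
    )
    return set_reference(profile, profile.reference_region)


def default_window_specs(
    z_start: float = 0.0,
    z_stop: float = 25.0,
    spacing: float = 1.0,
    k_z: float = 500.0 / 418.4,
    r_cyl: float = 2.5,
    k_fb: float = 5000.0 / 418.4,
) -> List[RestraintSpec]:
    """Umbrella layout: centres ``z_start..z_stop`` inclusive at ``spacing``.

    Defaults follow the fixed-charge protocol: 1 A spacing over 0-25 A with a
    500 kJ/mol/nm^2 z-bias (1.195 kcal/mol/A^2) and a 2.5 A cylinder with a
    5000 kJ/mol/nm^2 wall.
    """
    n = int(round((z_stop - z_start) / spacing)) + 1
    centers = z_start + spacing * np.arange(n)
    return [RestraintSpec(z_center=float(c), k_z=k_z, r_cyl=r_cyl, k_fb=k_fb) for c in centers]


def generate_umbrella_dataset(
    model: ModelPotential,
    windows: Sequence[RestraintSpec],
    params: BrownianParams,
) -> List[UmbrellaWindow]:
    """One Brownian-dynamics window per restraint.

    Window ``i`` uses seed ``params.seed + i`` and starts on the axis at its
    umbrella centre.  Duplicate centres are kept with a warning.
    """
    centers = [w.z_center for w in windows]
    if len(set(centers)) != len(centers):
        warnings.warn("duplicate window centers in layout; keeping all windows")
    out = []
    for i, spec in enumerate(windows):
        p_i = BrownianParams(
            diffusion=params.diffusion,
            dt=params.dt,
            n_steps=params.n_steps,
            seed=params.seed + i,
            initial_position=(0.0, 0.0, spec.z_center),
            max_drift=params.max_drift,
            sample_every=params.sample_every,
        )
        out.append(simulate_window(model, spec, p_i, label=f"w{i:03d}_z{spec.z_center:g}"))
    return out


def generate_host_geometry(
    ring_radius: float = 3.0,
    n_ring: int = 12,
    flank_atoms: Sequence[Sequence[float]] = (),
    charges: Optional[Sequence[float]] = None,
    vdw: Optional[Sequence] = None,
) -> HostGeometry:
    """Idealised host: ``n_ring`` cavity atoms evenly spaced on a circle.

    The ring lies in the z = 0 plane with its centroid at the origin, standing
    in for the inward-pointing CH carbons that define the cavity centre.
    Optional ``flank_atoms`` (with per-atom ``charges`` and ``vdw`` covering
    ring plus flank) support interaction-energy tests.
    """
    if n_ring < 3:
        raise ValueError("n_ring must be >= 3")
    angles = 2.0 * np.pi * np.arange(n_ring) / n_ring
    ring = np.column_stack(
        [ring_radius * np.cos(angles), ring_radius * np.sin(angles), np.zeros(n_ring)]
    )
    ring -= ring.mean(axis=0)  # exact centroid at origin
    all_atoms = ring if len(flank_atoms) == 0 else np.vstack([ring, np.asarray(flank_atoms, float)])
    return HostGeometry(
        cavity_atoms=ring,
        all_atoms=all_atoms,
        charges=None if charges is None else np.asarray(charges, float),
        vdw=vdw,
    )


def _uniform_in_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v / norms * r[:, None]


def _two_state_series(
    rng: np.random.Generator, times: np.ndarray, k_wet: float, k_dry: float
) -> np.ndarray:
    """Exact continuous-time two-state chain sampled at the frame times."""
    p_wet = k_wet / (k_wet + k_dry) if (k_wet + k_dry) > 0 else 1.0
    state = bool(rng.random() < p_wet)  # stationary initial state
    t_end = times[-1]
    switch_times = []
    t = times[0]
    s = state
    while t <= t_end:
        rate = k_dry if s else k_wet  # rate of leaving the current state
        if rate <= 0:
            break
        t = t + rng.exponential(1.0 / rate)
        switch_times.append(t)
        s = not s
    n_switches_before = np.searchsorted(np.asarray(switch_times), times, side="right")
    return np.where(n_switches_before % 2 == 0, state, not state)


def generate_solvent_frames(
    model: SolventModel,
    window: UmbrellaWindow,
    host: HostGeometry,
    seed: int = 0,
    frame_stride: int = 1,
) -> List[SolventFrame]:
    """Pseudo-solvent frames for the ion positions of one window.

    Per frame, the number of shell waters is Poisson with mean
    ``bulk_count_mean * s(d)`` (d = ion-cavity distance) and the waters are
    placed uniformly within ``shell_cutoff`` of the ion.  Independently, a
    two-state Markov chain decides whether the cavity is wetted; wetted frames
    carry one extra water uniform within ``cavity_radius`` of the cavity
    centre.  When the ion itself sits inside the cavity its shell waters can
    also wet the cavity; the Markov process is cleanly recoverable from
    windows where the ion stays outside.
    """
    if window.x is None or window.y is None:
        raise ValueError("window must carry x and y coordinates")
    rng = np.random.default_rng(seed)
    center = cavity_center(host)
    sel = slice(None, None, frame_stride)
    times = window.times[sel]
    ions = np.column_stack([window.x[sel], window.y[sel], window.z[sel]])

    d = np.linalg.norm(ions - center, axis=1)
    lam = model.bulk_count_mean * model.replacement_factor(d)
    counts = rng.poisson(lam)
    offsets = _uniform_in_ball(rng, int(counts.sum()), model.shell_cutoff)
    splits = np.cumsum(counts)[:-1]
    per_frame = np.split(offsets, splits)

    wet = _two_state_series(rng, times, model.k_wet, model.k_dry)
    cavity_offsets = _uniform_in_ball(rng, len(times), model.cavity_radius)

    frames = []
    for i, t in enumerate(times):
        waters = ions[i] + per_frame[i]
        if wet[i]:
            waters = np.vstack([waters, center + cavity_offsets[i]])
        frames.append(
            SolventFrame(
                time=float(t),
                ion=ions[i],
                waters=waters,
                host=host,
                z_dist=float(ions[i][2] - center[2]),
            )
        )
    return frames
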