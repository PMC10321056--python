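"""Fixed-charge pair potentials and interaction-energy profiles.

Two van der Waals functional forms are implemented, parameterised by the
minimum location ``r_min`` and well depth ``epsilon`` so they are directly
comparable:

* 12-6 Lennard-Jones, ``4 eps [(sigma/r)^12 - (sigma/r)^6]`` with
  ``sigma = r_min / 2^(1/6)`` and Lorentz-Berthelot combination (arithmetic
  sigma, geometric epsilon);
* buffered 14-7 (Halgren form, delta = 0.07, gamma = 0.12),
  ``eps * (1.07/(rho+0.07))^7 * (1.12/(rho^7+0.12) - 2)`` with
  ``rho = r/r_min``, using the cubic-mean r_min and HHG epsilon combination
  rules of its native polarizable-force-field ecosystem.

Both give exactly -epsilon at r = r_min.  Electrostatics is a plain vacuum
Coulomb term, 332.0637 q1 q2 / r kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import COULOMB_CONSTANT
from .geometry import HostGeometry

__all__ = [
    "VdwParams",
    "ChargedAtom",
    "lj_12_6",
    "buffered_14_7",
    "coulomb",
    "fit_lj_to_14_7",
    "interaction_profile",
]

BUFFER_DELTA = 0.07
BUFFER_GAMMA = 0.12


@dataclass(frozen=True)
class VdwParams:
    """van der Waals parameters: minimum location (A) and well depth (kcal/mol)."""

    r_min: float
    epsilon: float
    form: str = "lj_12_6"

    def __post_init__(self) -> None:
        if self.r_min <= 0:
            raise ValueError("r_min must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.form not in ("lj_12_6", "buffered_14_7"):
            raise ValueError(f"unknown vdW form {self.form!r}")

    @property
    def sigma(self) -> float:
        """12-6 zero-crossing distance, r_min / 2^(1/6)."""
        return self.r_min / 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ChargedAtom:
    position: Tuple[float, float, float]
    charge: float
    vdw: VdwParams

    def __post_init__(self) -> None:
        if not math.isfinite(self.charge):
            raise ValueError("charge must be finite")


def _combine_lj(p1: VdwParams, p2: VdwParams) -> Tuple[float, float]:
    sigma = 0.5 * (p1.sigma + p2.sigma)
    eps = math.sqrt(p1.epsilon * p2.epsilon)
    return sigma, eps


def _combine_14_7(p1: VdwParams, p2: VdwParams) -> Tuple[float, float]:
    r1, r2 = p1.r_min, p2.r_min
    r_min = (r1**3 + r2**3) / (r1**2 + r2**2)  # cubic-mean rule
    e1, e2 = p1.epsilon, p2.epsilon
    if e1 == 0.0 or e2 == 0.0:
        eps = 0.0
    else:
        eps = 4.0 * e1 * e2 / (math.sqrt(e1) + math.sqrt(e2)) ** 2  # HHG rule
    return r_min, eps


def lj_12_6(r, p1: VdwParams, p2: Optional[VdwParams] = None):
    """12-6 Lennard-Jones pair energy (kcal/mol); ``p2`` defaults to ``p1``."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    sigma, eps = _combine_lj(p1, p2 or p1)
    sr6 = (sigma / r) ** 6
    out = 4.0 * eps * (sr6**2 - sr6)
    return float(out) if out.ndim == 0 else out


def buffered_14_7(r, p1: VdwParams, p2: Optional[VdwParams] = None):
    """Buffered 14-7 pair energy (kcal/mol); ``p2`` defaults to ``p1``."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    r_min, eps = _combine_14_7(p1, p2 or p1)
    rho = r / r_min
    out = (
        eps
        * ((1.0 + BUFFER_DELTA) / (rho + BUFFER_DELTA)) ** 7
        * ((1.0 + BUFFER_GAMMA) / (rho**7 + BUFFER_GAMMA) - 2.0)
    )
    return float(out) if out.ndim == 0 else out


def coulomb(r, q1: float, q2: float):
    """Vacuum Coulomb energy (kcal/mol), charges in e, r in A."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    out = COULOMB_CONSTANT * q1 * q2 / r
    return float(out) if out.ndim == 0 else out


def _pair_energy(r, p1: VdwParams, p2: VdwParams):
    fn = buffered_14_7 if p1.form == "buffered_14_7" else lj_12_6
    return fn(r, p1, p2)


def fit_lj_to_14_7(
    target: VdwParams,
    r_range: Sequence[float],
    weights: Optional[Sequence[float]] = None,
) -> Tuple[VdwParams, float]:
    """Least-squares fit of a 12-6 form to a pair curve on a grid.

    The target curve is the like-pair energy of ``target`` (either form); the
    result is the 12-6 ``(r_min, epsilon)`` minimising the weighted residual,
    plus the residual 2-norm.  Deterministic: the optimiser starts from the
    target parameters.
    """
    r = np.asarray(r_range, dtype=float)
    if r.min() > target.r_min or r.max() < target.r_min:
        raise ValueError("r_range must cover the target minimum")
    w = np.ones_like(r) if weights is None else np.sqrt(np.asarray(weights, dtype=float))
    y = _pair_energy(r, target, target)

    def resid(p):
        trial = VdwParams(r_min=p[0], epsilon=p[1], form="lj_12_6")
        return w * (lj_12_6(r, trial) - y)

    sol = least_squares(
        resid, x0=[target.r_min, max(target.epsilon, 1e-12)],
        bounds=([1e-6, 0.0], [np.inf, np.inf]),
    )
    if not sol.success:
        raise RuntimeError(f"12-6 fit did not converge: {sol.message}; residual {sol.cost:.3e}")
    fitted = VdwParams(r_min=float(sol.x[0]), epsilon=float(sol.x[1]), form="lj_12_6")
    return fitted, float(np.linalg.norm(sol.fun))


def interaction_profile(
    frames: Sequence,
    host: HostGeometry,
    guest_charge: float,
    guest_vdw: VdwParams,
    reference_z: float = 15.0,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Guest-host interaction energy binned along the reaction coordinate.

    For each frame the total pairwise guest-host energy is split into vdW and
    Coulomb components and binned by ``z_dist``; each component is shifted so
    the bin containing ``reference_z`` (bulk) is zero.  ``frames`` need
    ``.ion`` and ``.z_dist`` attributes (e.g. :class:`SolventFrame`).
    """
    if host.charges is None or host.vdw is None:
        raise ValueError("host atoms must carry charges and vdW parameters")
    if len(frames) == 0:
        raise ValueError("at least one frame is required")
    z = np.array([f.z_dist for f in frames])
    e_vdw = np.empty(len(frames))
    e_coul = np.empty(len(frames))
    for i, f in enumerate(frames):
        d = np.linalg.norm(host.all_atoms - np.asarray(f.ion, dtype=float), axis=1)
        ev = 0.0
        ec = 0.0
        for j, dist in enumerate(d):
            ev += _pair_energy(float(dist), guest_vdw, host.vdw[j])
            ec += coulomb(float(dist), guest_charge, float(host.charges[j]))
        e_vdw[i] = ev
        e_coul[i] = ec

    lo = math.floor(z.min() / bin_width)
    hi = math.ceil(z.max() / bin_width)
    if hi <= lo:
        hi = lo + 1
    edges = bin_width * np.arange(lo, hi + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, len(edges) - 2)
    centers = 0.5 * (edges[:-1] + edges[1:])

    rows = []
    for b in range(len(centers)):
        m = idx == b
        n = int(np.count_nonzero(m))
        rows.append(
            {
                "z": centers[b],
                "E_vdw": e_vdw[m].mean() if n else np.nan,
                "E_coul": e_coul[m].mean() if n else np.nan,
                "n_frames": n,
            }
        )
    df = pd.DataFrame(rows)

    if not (edges[0] <= reference_z <= edges[-1]):
        raise ValueError(
            f"reference z = {reference_z} A lies outside the sampled range "
            f"[{edges[0]}, {edges[-1]}]"
        )
    ref_idx = int(np.clip(np.digitize(reference_z, edges) - 1, 0, len(centers) - 1))
    if df.loc[ref_idx, "n_frames"] == 0:
        raise ValueError(f"reference bin at z = {reference_z} A is unoccupied")
    df["E_vdw"] -= df.loc[ref_idx, "E_vdw"]
    df["E_coul"] -= df.loc[ref_idx, "E_coul"]
    df["E_total"] = df["E_vdw"] + df["E_coul"]
    return df[["z", "E_vdw", "E_coul", "E_total", "n_frames"]]
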