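"""Standard-state binding free energies from a referenced PMF.

Two estimators are provided.  The headline estimator takes the minimum of the
bulk-referenced, block-averaged PMF as the binding free energy (with the block
scatter of the minimum as the error), plus the cylindrical-restraint
standard-state correction

    dG_corr = -RT ln(pi R_cyl^2 / A0),

where A0 = pi r0^2 ~= 170 A^2 is the standard surface built from the radius r0
of a sphere of standard volume 1661 A^3 (one solute per 1661 A^3 at 1 M).
When the cylinder cross-section equals A0 the correction vanishes.

The secondary, cross-check estimator integrates the PMF over the binding site:

    K_b = pi R_cyl^2 * Integral_site exp(-W(z)/RT) dz,     dG = -RT ln(C0 K_b),

with C0 = 1/1661 A^-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .constants import DEFAULT_TEMPERATURE, STANDARD_SURFACE, STANDARD_VOLUME, thermal_energy
from .wham import PMFProfile

__all__ = [
    "StandardState",
    "BindingEstimate",
    "standard_area",
    "cylinder_correction",
    "dg_from_minimum",
    "dg_from_integral",
]


@dataclass(frozen=True)
class StandardState:
    """Standard-state constants (1 M): volume 1661 A^3, surface ~170 A^2."""

    volume: float = STANDARD_VOLUME
    surface: float = STANDARD_SURFACE
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def concentration(self) -> float:
        """C0 in A^-3."""
        return 1.0 / self.volume

    @property
    def r0(self) -> float:
        """Radius of the sphere of standard volume (A)."""
        return (3.0 * self.volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class BindingEstimate:
    """Binding free-energy components (kcal/mol)."""

    dG_min: Optional[float]
    dG_corr: float
    dG_total: float
    dG_sd: Optional[float]
    z_min: Optional[float]
    method: str
    r_cyl: Optional[float] = None
    temperature: float = DEFAULT_TEMPERATURE


def standard_area(volume: float) -> float:
    """pi*r^2 for the sphere of the given volume (A^3 -> A^2)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return math.pi * (3.0 * volume / (4.0 * math.pi)) ** (2.0 / 3.0)


def cylinder_correction(
    r_cyl: float,
    temperature: float = DEFAULT_TEMPERATURE,
    a0: float = STANDARD_SURFACE,
) -> float:
    """Standard-state correction -RT ln(pi r_cyl^2 / A0) in kcal/mol.

    Positive for cylinders narrower than the standard surface, monotonically
    decreasing in r_cyl, zero exactly at pi r_cyl^2 = A0.
    """
    if r_cyl <= 0:
        raise ValueError("r_cyl must be positive")
    rt = thermal_energy(temperature)
    return -rt * math.log(math.pi * r_cyl**2 / a0)


def _require_referenced(profile: PMFProfile, name: str) -> None:
    if not profile.is_referenced():
        raise ValueError(f"{name} must be referenced to the bulk region before use")


def dg_from_minimum(
    mean_profile: PMFProfile,
    block_profiles: Sequence[PMFProfile] = (),
    r_cyl: Optional[float] = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> BindingEstimate:
    """Minimum-of-the-PMF binding estimate.

    ``dG_min`` is the minimum of the mean profile over occupied bins (ties
    broken toward smaller |z|), ``dG_sd`` the standard deviation of the
    per-block minima (absent with fewer than two blocks).  If ``r_cyl`` is
    given the cylinder correction is added; it is treated as exact, so the
    uncertainty carries only the block scatter.
    """
    _require_referenced(mean_profile, "mean profile")
    dg_min, z_min = mean_profile.minimum()
    dg_sd: Optional[float] = None
    if len(block_profiles) >= 2:
        minima = []
        for p in block_profiles:
            _require_referenced(p, "block profile")
            minima.append(p.minimum()[0])
        dg_sd = float(np.std(minima, ddof=1))
    dg_corr = cylinder_correction(r_cyl, temperature) if r_cyl is not None else 0.0
    return BindingEstimate(
        dG_min=dg_min,
        dG_corr=dg_corr,
        dG_total=dg_min + dg_corr,
        dG_sd=dg_sd,
        z_min=z_min,
        method="minimum",
        r_cyl=r_cyl,
        temperature=temperature,
    )


def dg_from_integral(
    profile: PMFProfile,
    r_cyl: float,
    site_bounds: Tuple[float, float],
    temperature: float = DEFAULT_TEMPERATURE,
    standard_state: StandardState = StandardState(),
) -> BindingEstimate:
    """Integral (binding-constant) estimate over a declared binding site.

    Trapezoid quadrature of exp(-W/RT) over the bins whose centres fall in
    ``site_bounds``; every such bin must be occupied.
    """
    _require_referenced(profile, "profile")
    lo, hi = site_bounds
    m = (profile.z_grid >= lo) & (profile.z_grid <= hi)
    if not np.any(m):
        raise ValueError(f"site bounds [{lo}, {hi}] contain no bins")
    if np.any(~profile.occupied_mask[m]):
        raise ValueError(f"site bounds [{lo}, {hi}] contain masked (unoccupied) bins")
    rt = thermal_energy(temperature)
    z = profile.z_grid[m]
    integrand = np.exp(-profile.W[m] / rt)
    kb = math.pi * r_cyl**2 * float(np.trapezoid(integrand, z))
    dg_total = -rt * math.log(standard_state.concentration * kb)
    return BindingEstimate(
        dG_min=None,
        dG_corr=0.0,
        dG_total=dg_total,
        dG_sd=None,
        z_min=None,
        method="integral",
        r_cyl=r_cyl,
        temperature=temperature,
    )
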