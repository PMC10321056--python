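"""Reaction-coordinate geometry and restraint energies.

The reaction coordinate for ion passage through a macrocyclic cavity is the
signed difference between the z-coordinate of the ion and the z-coordinate of
the cavity centre, with the cavity centre defined as the unweighted centroid
(centre of geometry) of the inward-pointing cavity atoms.  Lateral motion is
confined by a flat-bottom cylinder: zero potential for in-plane distances
r_perp <= r_cyl, half-harmonic beyond the wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import KJ_NM2_TO_KCAL_A2

__all__ = [
    "HostGeometry",
    "RestraintSpec",
    "cavity_center",
    "reaction_coordinate",
    "bias_energy",
    "bias_gradient",
    "convert_force_constant",
]

#: Canonical unit strings accepted by :func:`convert_force_constant`.
_FORCE_CONSTANT_UNITS = {
    "kJ/mol/nm^2": 1.0,
    "kcal/mol/A^2": 418.4,  # value in kJ/mol/nm^2 per 1 kcal/mol/A^2
}


@dataclass
class HostGeometry:
    """Host (macrocycle) geometry.

    ``cavity_atoms`` are the inward-pointing atoms whose centroid defines the
    cavity centre; they must be a subset of ``all_atoms``.  ``charges`` (e) and
    ``vdw`` (per-atom van der Waals parameters) are optional and only needed
    for interaction-energy profiles.
    """

    cavity_atoms: np.ndarray
    all_atoms: np.ndarray
    charges: Optional[np.ndarray] = None
    vdw: Optional[Sequence] = None
    cavity_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.cavity_atoms = np.atleast_2d(np.asarray(self.cavity_atoms, dtype=float))
        self.all_atoms = np.atleast_2d(np.asarray(self.all_atoms, dtype=float))
        self.cavity_axis = np.asarray(self.cavity_axis, dtype=float)
        if self.cavity_atoms.size == 0:
            raise ValueError("cavity_atoms must be non-empty")
        if not np.isclose(np.linalg.norm(self.cavity_axis), 1.0):
            raise ValueError("cavity_axis must have unit norm")
        # subset check: every cavity atom must appear among all_atoms
        for atom in self.cavity_atoms:
            if not np.any(np.all(np.isclose(self.all_atoms, atom, atol=1e-9), axis=1)):
                raise ValueError("cavity_atoms must be a subset of all_atoms")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape[0] != self.all_atoms.shape[0]:
                raise ValueError("one charge per atom required")


@dataclass(frozen=True)
class RestraintSpec:
    """Umbrella + flat-bottom cylinder restraint for one window.

    Parameters
    ----------
    z_center : float
        Target of the harmonic z-umbrella (A, signed).
    k_z : float
        Umbrella force constant (kcal/mol/A^2).
    r_cyl : float
        Flat-bottom cylinder radius (A).
    k_fb : float
        Wall force constant beyond the cylinder (kcal/mol/A^2); the wall is
        half-harmonic, continuous and once-differentiable at r_perp = r_cyl.
    """

    z_center: float
    k_z: float
    r_cyl: float = 2.5
    k_fb: float = 5000.0 * KJ_NM2_TO_KCAL_A2
    position_restraints: tuple = ()

    def __post_init__(self) -> None:
        if self.k_z < 0 or self.k_fb < 0:
            raise ValueError("force constants must be non-negative")
        if self.r_cyl <= 0:
            raise ValueError("r_cyl must be positive")


def cavity_center(host: HostGeometry) -> np.ndarray:
    """Unweighted centroid (centre of geometry) of the cavity atoms."""
    if host.cavity_atoms.size == 0:
        raise ValueError("host has no cavity atoms")
    return host.cavity_atoms.mean(axis=0)


def reaction_coordinate(ion, center):
    """Signed axial distance and in-plane distance of the ion from the cavity.

    Returns ``(z_dist, r_perp)`` with ``z_dist = ion_z - center_z`` (signed)
    and ``r_perp`` the distance from the cavity axis in the xy-plane.
    """
    ion = np.asarray(ion, dtype=float)
    center = np.asarray(center, dtype=float)
    z_dist = ion[2] - center[2]
    r_perp = float(np.hypot(ion[0] - center[0], ion[1] - center[1]))
    return float(z_dist), r_perp


def bias_energy(restraint: RestraintSpec, z_dist, r_perp):
    """Total restraint energy (kcal/mol) at the given reaction coordinates.

    ``0.5*k_z*(z_dist - z_center)^2`` plus, outside the cylinder,
    ``0.5*k_fb*(r_perp - r_cyl)^2``; zero radial term inside.
    """
    z_dist = np.asarray(z_dist, dtype=float)
    r_perp = np.asarray(r_perp, dtype=float)
    e_z = 0.5 * restraint.k_z * (z_dist - restraint.z_center) ** 2
    over = np.maximum(r_perp - restraint.r_cyl, 0.0)
    e_r = 0.5 * restraint.k_fb * over**2
    out = e_z + e_r
    return float(out) if out.ndim == 0 else out


def bias_gradient(restraint: RestraintSpec, position, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Cartesian gradient of :func:`bias_energy` at ``position`` (kcal/mol/A)."""
    position = np.asarray(position, dtype=float)
    center = np.asarray(center, dtype=float)
    dx, dy = position[0] - center[0], position[1] - center[1]
    r_perp = np.hypot(dx, dy)
    g = np.zeros(3)
    g[2] = restraint.k_z * (position[2] - center[2] - restraint.z_center)
    if r_perp > restraint.r_cyl:
        coeff = restraint.k_fb * (r_perp - restraint.r_cyl) / r_perp
        g[0] = coeff * dx
        g[1] = coeff * dy
    return g


def convert_force_constant(value: float, from_units: str, to_units: str) -> float:
    """Convert a force constant between kJ/mol/nm^2 and kcal/mol/A^2.

    The exact factor between the two is 418.4 (4.184 J/cal times 100 A^2/nm^2);
    round trips are identities.
    """
    for unit in (from_units, to_units):
        if unit not in _FORCE_CONSTANT_UNITS:
            raise ValueError(
                f"unknown force-constant unit {unit!r}; "
                f"expected one of {sorted(_FORCE_CONSTANT_UNITS)}"
            )
    if from_units == to_units:
        return value
    return value * _FORCE_CONSTANT_UNITS[from_units] / _FORCE_CONSTANT_UNITS[to_units]
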