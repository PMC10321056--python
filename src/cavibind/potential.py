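"""Ground-truth model potentials for the synthetic host-guest system.

The synthetic free-energy landscape is separable,

    U(x, y, z) = U_z(z) + 0.5 * radial_k * (x^2 + y^2),

with the axial part a sum of Gaussians U_z(z) = sum_i a_i exp(-(z-c_i)^2 / 2w_i^2).
Negative amplitudes are wells (binding sites), positive amplitudes barriers;
all terms decay, so U_z -> 0 in bulk.  Separability makes the exact PMF along z
equal to U_z up to an additive constant, which is what the estimators are
benchmarked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .constants import DEFAULT_TEMPERATURE

__all__ = ["ModelPotential", "default_landscape"]


@dataclass(frozen=True)
class ModelPotential:
    """Separable model energy surface (kcal/mol, A, K)."""

    gaussians: Tuple[Tuple[float, float, float], ...] = ()
    radial_k: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "gaussians", tuple((float(a), float(c), float(w)) for a, c, w in self.gaussians)
        )
        if any(w <= 0 for _, _, w in self.gaussians):
            raise ValueError("Gaussian widths must be positive")
        if self.radial_k < 0:
            raise ValueError("radial_k must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def u_z(self, z):
        """Axial potential U_z(z) in kcal/mol (vectorised)."""
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for a, c, w in self.gaussians:
            u = u + a * np.exp(-0.5 * ((z - c) / w) ** 2)
        return float(u) if u.ndim == 0 else u

    def du_z(self, z):
        """dU_z/dz in kcal/mol/A."""
        z = np.asarray(z, dtype=float)
        g = np.zeros_like(z)
        for a, c, w in self.gaussians:
            g = g + a * (-(z - c) / w**2) * np.exp(-0.5 * ((z - c) / w) ** 2)
        return float(g) if g.ndim == 0 else g

    def energy(self, x, y, z):
        """Full separable energy U(x,y,z)."""
        return self.u_z(z) + 0.5 * self.radial_k * (np.asarray(x) ** 2 + np.asarray(y) ** 2)

    def gradient(self, position) -> np.ndarray:
        """Cartesian gradient of U at a single point."""
        x, y, z = position
        return np.array([self.radial_k * x, self.radial_k * y, self.du_z(z)])

    def gaussian_arrays(self):
        """(amplitudes, centers, widths) as float arrays, for the fast sampler."""
        if not self.gaussians:
            z = np.zeros(0)
            return z, z.copy(), z.copy() + 1.0
        a, c, w = (np.array(v, dtype=float) for v in zip(*self.gaussians))
        return a, c, w


def default_landscape(temperature: float = DEFAULT_TEMPERATURE) -> ModelPotential:
    """Default synthetic landscape used by fixtures and the acceptance checks.

    A central binding well of -6 kcal/mol at z = 0, flanking wells of
    -4 kcal/mol at |z| = 3.5 A, and a flat bulk plateau beyond ~12 A — the
    qualitative shape of an anion PMF through a hydrophobic macrocycle cavity
    (central pose plus portal poses).
    """
    return ModelPotential(
        gaussians=((-6.0, 0.0, 1.2), (-4.0, -3.5, 1.0), (-4.0, 3.5, 1.0)),
        radial_k=1.0,
        temperature=temperature,
    )
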