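"""Overdamped Langevin (Brownian dynamics) sampler for biased windows.

Euler-Maruyama integration of

    dr = -(D/RT) * grad(U + U_bias) * dt + sqrt(2 D dt) * xi,

with xi a standard normal per coordinate.  There is no inertia and no
hydrodynamic anisotropy: only the equilibrium distribution matters for PMF
recovery, and the overdamped scheme samples exp(-(U+U_bias)/RT) for small
enough dt.

Stability is monitored through the deterministic drift term
dt*D*|grad U|/RT, which is the step-size-dependent quantity; the random
displacement is unbounded by construction and is not a stability signal.  A
window aborts with a diagnostic if the drift magnitude ever exceeds
``max_drift`` (default 0.5 A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .constants import thermal_energy
from .geometry import RestraintSpec
from .potential import ModelPotential
from .wham import UmbrellaWindow

__all__ = ["BrownianParams", "simulate_window"]


@dataclass(frozen=True)
class BrownianParams:
    """Integration parameters for one Brownian-dynamics window.

    diffusion : A^2/ps; dt : ps; n_steps : number of integration steps;
    seed : RNG seed (all randomness flows from it); initial_position : A;
    max_drift : abort threshold on the per-step deterministic drift (A);
    sample_every : record every n-th step (step 0 is always recorded).
    """

    diffusion: float
    dt: float
    n_steps: int
    seed: int
    initial_position: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    max_drift: float = 0.5
    sample_every: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.diffusion < 0:
            raise ValueError("diffusion must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")


@njit(cache=False)
def _integrate(x0, y0, z0, n_steps, sample_every, dt, mobility, noise_scale,
               amps, cents, widths, radial_k, k_z, z_center, r_cyl, k_fb,
               noise, max_drift):  # pragma: no cover - exercised via simulate_window
    n_rec = n_steps // sample_every + 1
    out = np.empty((n_rec, 3))
    out[0, 0] = x0
    out[0, 1] = y0
    out[0, 2] = z0
    x, y, z = x0, y0, z0
    rec = 1
    for i in range(n_steps):
        gx = radial_k * x
        gy = radial_k * y
        gz = 0.0
        for g in range(amps.shape[0]):
            dz = z - cents[g]
            w2 = widths[g] * widths[g]
            gz += amps[g] * (-dz / w2) * np.exp(-0.5 * dz * dz / w2)
        gz += k_z * (z - z_center)
        r_perp = np.sqrt(x * x + y * y)
        if k_fb > 0.0 and r_perp > r_cyl:
            coeff = k_fb * (r_perp - r_cyl) / r_perp
            gx += coeff * x
            gy += coeff * y
        dx = -mobility * gx * dt
        dy = -mobility * gy * dt
        dz_ = -mobility * gz * dt
        if np.sqrt(dx * dx + dy * dy + dz_ * dz_) > max_drift:
            return out[:rec], i
        x += dx + noise_scale * noise[i, 0]
        y += dy + noise_scale * noise[i, 1]
        z += dz_ + noise_scale * noise[i, 2]
        if (i + 1) % sample_every == 0:
            out[rec, 0] = x
            out[rec, 1] = y
            out[rec, 2] = z
            rec += 1
    return out[:rec], -1


def simulate_window(
    model: ModelPotential,
    restraint: Optional[RestraintSpec],
    params: BrownianParams,
    label: str = "",
) -> UmbrellaWindow:
    """Simulate one (possibly unbiased) umbrella window.

    Returns the full (t, z, x, y) series including the initial point.
    Identical seeds reproduce identical trajectories bit-for-bit.

    Raises
    ------
    RuntimeError
        If the deterministic drift per step exceeds ``params.max_drift``
        (step-size instability).
    """
    rt = thermal_energy(model.temperature)
    mobility = params.diffusion / rt
    noise_scale = np.sqrt(2.0 * params.diffusion * params.dt)
    amps, cents, widths = model.gaussian_arrays()
    if restraint is None:
        k_z, z_center, r_cyl, k_fb = 0.0, 0.0, 1.0, 0.0
    else:
        k_z, z_center, r_cyl, k_fb = (
            restraint.k_z,
            restraint.z_center,
            restraint.r_cyl,
            restraint.k_fb,
        )
    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal((params.n_steps, 3))
    x0, y0, z0 = (float(v) for v in params.initial_position)
    traj, fail = _integrate(
        x0, y0, z0, params.n_steps, params.sample_every, params.dt, mobility,
        noise_scale, amps, cents, widths, model.radial_k, k_z, z_center,
        r_cyl, k_fb, noise, params.max_drift,
    )
    if fail >= 0:
        raise RuntimeError(
            f"window {label or z_center}: deterministic drift exceeded "
            f"{params.max_drift} A at step {fail}; reduce dt or diffusion"
        )
    times = np.arange(traj.shape[0]) * (params.dt * params.sample_every)
    return UmbrellaWindow(
        restraint=restraint,
        times=times,
        z=traj[:, 2].copy(),
        x=traj[:, 0].copy(),
        y=traj[:, 1].copy(),
        label=label,
    )
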