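import numpy as np
import pytest

from cavibind import (
    BrownianParams,
    ModelPotential,
    PMFProfile,
    RestraintSpec,
    UmbrellaWindow,
    default_landscape,
    generate_host_geometry,
    set_reference,
)


@pytest.fixture(scope="session")
def landscape():
    return default_landscape()


@pytest.fixture(scope="session")
def host_ring():
    """12-carbon ring of radius 3 A in the z = 0 plane."""
    return generate_host_geometry(ring_radius=3.0, n_ring=12)


@pytest.fixture
def flat_model():
    return ModelPotential(gaussians=(), radial_k=1.0)


def make_profile(z_grid, w, reference_region=None):
    """Referenced PMFProfile on a given grid (test helper)."""
    z_grid = np.asarray(z_grid, dtype=float)
    w = np.asarray(w, dtype=float)
    ref = reference_region or (float(z_grid.max() - 2.0), float(z_grid.max()))
    profile = PMFProfile(
        z_grid=z_grid,
        W=w,
        W_sd=None,
        reference_region=ref,
        occupied_mask=np.isfinite(w),
    )
    return set_reference(profile, ref)


@pytest.fixture
def profile_factory():
    return make_profile


def make_window(z, times=None, restraint=None, x=None, y=None, label=""):
    z = np.asarray(z, dtype=float)
    if times is None:
        times = np.arange(z.size, dtype=float)
    return UmbrellaWindow(restraint=restraint, times=times, z=z, x=x, y=y, label=label)


@pytest.fixture
def window_factory():
    return make_window


@pytest.fixture(scope="session")
def small_dataset(landscape):
    """Six short biased windows over the central well, for fast WHAM tests."""
    from cavibind import generate_umbrella_dataset

    specs = [RestraintSpec(z_center=float(c), k_z=2.0) for c in np.arange(0.0, 6.0, 1.0)]
    params = BrownianParams(diffusion=1.0, dt=0.01, n_steps=20_000, seed=42)
    return generate_umbrella_dataset(landscape, specs, params)
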