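"""Ground-truth potentials, analytic PMF and synthetic generators."""

import numpy as np
import pytest

from cavibind import (
    BrownianParams,
    ModelPotential,
    RestraintSpec,
    SolventModel,
    analytic_pmf,
    cavity_center,
    classify_wetting,
    count_shell,
    default_window_specs,
    generate_host_geometry,
    generate_solvent_frames,
    generate_umbrella_dataset,
    thermal_energy,
)
from cavibind.io import write_window


class TestAnalyticPmf:
    def test_flat_potential_gives_zero_profile(self):
        model = ModelPotential(gaussians=(), radial_k=1.0)
        prof = analytic_pmf(model, 2.5, np.linspace(-10, 10, 101))
        np.testing.assert_allclose(prof.W, 0.0, atol=1e-12)

    def test_separability_single_well(self):
        model = ModelPotential(gaussians=((-5.0, 0.0, 1.5),), radial_k=1.0)
        grid = np.linspace(-15, 15, 301)
        prof = analytic_pmf(model, 2.5, grid, reference_region=(13.0, 15.0))
        w0 = prof.W[np.argmin(np.abs(grid))]
        w_bulk = prof.W[-1]
        assert w0 - w_bulk == pytest.approx(-5.0, abs=1e-6)

    def test_matches_dense_quadrature_oracle(self):
        """Independent polar trapezoid quadrature of the radial integral."""
        model = ModelPotential(
            gaussians=((-4.0, 0.0, 1.0), (2.0, 3.0, 0.8)), radial_k=1.5
        )
        r_cyl = 2.5
        grid = np.linspace(-6, 10, 33)
        rt = thermal_energy(model.temperature)

        r = np.linspace(0.0, r_cyl, 200_001)
        radial = 2.0 * np.pi * np.trapezoid(
            r * np.exp(-0.5 * model.radial_k * r**2 / rt), r
        )
        w_oracle = model.u_z(grid) - rt * np.log(radial)
        ref = (8.0, 10.0)
        w_oracle -= w_oracle[(grid >= ref[0]) & (grid <= ref[1])].mean()

        prof = analytic_pmf(model, r_cyl, grid, reference_region=ref)
        np.testing.assert_allclose(prof.W, w_oracle, atol=1e-4)

    def test_separability_invariant_whole_grid(self):
        """W equals U_z up to a constant whenever radial_k > 0."""
        model = ModelPotential(gaussians=((-6.0, 0.0, 1.2), (1.0, 4.0, 2.0)), radial_k=0.7)
        grid = np.linspace(-12, 12, 241)
        prof = analytic_pmf(model, 3.5, grid)
        diff = prof.W - model.u_z(grid)
        np.testing.assert_allclose(diff, diff[0], atol=1e-10)

    def test_unbounded_plane_without_confinement_rejected(self):
        model = ModelPotential(gaussians=(), radial_k=0.0)
        with pytest.raises(ValueError, match="divergent"):
            analytic_pmf(model, None, np.linspace(0, 10, 11))

    def test_decreasing_grid_rejected(self):
        model = ModelPotential(gaussians=(), radial_k=1.0)
        with pytest.raises(ValueError):
            analytic_pmf(model, 2.5, [3.0, 2.0, 1.0])


class TestUmbrellaDataset:
    def test_fixed_charge_layout_covers_range(self, flat_model):
        """26 windows, 1 A spacing, 500 kJ/mol/nm^2 bias: each window's mean
        sits within 1 A of its umbrella centre on a flat landscape."""
        specs = default_window_specs(z_start=0.0, z_stop=25.0, spacing=1.0)
        assert len(specs) == 26
        assert specs[0].k_z == pytest.approx(1.195, abs=5e-4)
        params = BrownianParams(diffusion=1.0, dt=0.01, n_steps=5000, seed=3)
        windows = generate_umbrella_dataset(flat_model, specs, params)
        for w in windows:
            assert abs(w.z.mean() - w.restraint.z_center) < 1.0

    def test_polarizable_style_layout(self):
        specs = default_window_specs(z_start=-15.0, z_stop=15.0, spacing=0.5, k_z=2.0)
        assert len(specs) == 60 + 1
        centers = [s.z_center for s in specs]
        assert centers[0] == -15.0 and centers[-1] == 15.0
        assert np.allclose(np.diff(centers), 0.5)

    def test_empty_window_list(self, flat_model):
        params = BrownianParams(diffusion=1.0, dt=0.01, n_steps=10, seed=0)
        assert generate_umbrella_dataset(flat_model, [], params) == []

    def test_duplicate_centers_warn_but_kept(self, flat_model):
        specs = [RestraintSpec(z_center=1.0, k_z=1.0)] * 2
        params = BrownianParams(diffusion=1.0, dt=0.01, n_steps=50, seed=0)
        with pytest.warns(UserWarning, match="duplicate"):
            windows = generate_umbrella_dataset(flat_model, specs, params)
        assert len(windows) == 2

    def test_datasets_byte_identical_for_same_seed(self, flat_model, tmp_path):
        specs = [RestraintSpec(z_center=float(c), k_z=1.0) for c in range(3)]
        params = BrownianParams(diffusion=1.0, dt=0.01, n_steps=200, seed=9)
        files = []
        for run in ("a", "b"):
            windows = generate_umbrella_dataset(flat_model, specs, params)
            path = tmp_path / f"{run}.dat"
            for w in windows:
                write_window(path, w)
            files.append(path.read_bytes())
        assert files[0] == files[1]


class TestHostGeometry:
    def test_ring_centroid_machine_precision(self):
        host = generate_host_geometry(ring_radius=3.0, n_ring=12)
        np.testing.assert_allclose(cavity_center(host), 0.0, atol=1e-15)

    def test_square_ring_positions(self):
        host = generate_host_geometry(ring_radius=1.0, n_ring=4)
        expected = np.array([(1, 0, 0), (0, 1, 0), (-1, 0, 0), (0, -1, 0)], dtype=float)
        np.testing.assert_allclose(host.cavity_atoms, expected, atol=1e-15)

    @pytest.mark.parametrize("n_ring, radius", [(5, 2.0), (12, 3.0), (7, 1.3)])
    def test_regular_polygon_equal_neighbour_distances(self, n_ring, radius):
        host = generate_host_geometry(ring_radius=radius, n_ring=n_ring)
        atoms = host.cavity_atoms
        d = np.linalg.norm(atoms - np.roll(atoms, -1, axis=0), axis=1)
        np.testing.assert_allclose(d, d[0], rtol=1e-12)

    def test_too_few_ring_atoms_rejected(self):
        with pytest.raises(ValueError):
            generate_host_geometry(ring_radius=3.0, n_ring=2)


class TestSolventGenerator:
    def _window_at(self, z_value, n_frames, dt=0.2):
        from cavibind import UmbrellaWindow

        t = np.arange(n_frames) * dt
        zero = np.zeros(n_frames)
        return UmbrellaWindow(restraint=None, times=t, z=np.full(n_frames, float(z_value)),
                              x=zero, y=zero)

    def test_absorbing_wet_state(self, host_ring):
        model = SolventModel(k_wet=1.0, k_dry=0.0)
        window = self._window_at(15.0, 500)
        frames = generate_solvent_frames(model, window, host_ring, seed=5)
        trace = classify_wetting(frames, cavity_cutoff=3.0)
        assert trace.fraction_dewetted == 0.0

    def test_bulk_shell_count_recovers_expectation(self, host_ring):
        """Far from the cavity, the mean shell count approaches bulk_count_mean."""
        model = SolventModel(bulk_count_mean=6.0, k_wet=0.0, k_dry=1.0)
        window = self._window_at(20.0, 10_000)
        frames = generate_solvent_frames(model, window, host_ring, seed=6)
        counts = [count_shell(f, water_cutoff=model.shell_cutoff)[0] for f in frames]
        se = np.sqrt(6.0 / len(frames))
        assert abs(np.mean(counts) - 6.0) < 3 * se

    def test_equal_rates_give_half_wetted(self, host_ring):
        model = SolventModel(k_wet=0.05, k_dry=0.05)
        window = self._window_at(15.0, 20_000)
        frames = generate_solvent_frames(model, window, host_ring, seed=7)
        trace = classify_wetting(frames, cavity_cutoff=3.0)
        # time-average variance of a two-state chain: 1/(4 k T) at equal rates
        se = np.sqrt(1.0 / (4 * 0.05 * trace.duration))
        assert abs(trace.fraction_dewetted - 0.5) < 3 * se

    def test_replacement_factor_shape(self):
        model = SolventModel(cavity_radius=3.0, replacement_halfwidth=1.0)
        assert model.replacement_factor(3.0) == pytest.approx(0.5)
        assert model.replacement_factor(30.0) == pytest.approx(1.0, abs=1e-9)
        assert model.replacement_factor(0.0) < 0.05

    def test_frames_reproducible(self, host_ring):
        model = SolventModel()
        window = self._window_at(10.0, 100)
        a = generate_solvent_frames(model, window, host_ring, seed=3)
        b = generate_solvent_frames(model, window, host_ring, seed=3)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.waters, fb.waters)


def test_sampler_boltzmann_distribution_small():
    """Short-run sanity: unrestrained 1-D histogram tracks exp(-U/RT)
    (the full goodness-of-fit check runs in the acceptance suite)."""
    model = ModelPotential(gaussians=((-1.0, 0.0, 2.0), (50.0, -6.0, 1.0), (50.0, 6.0, 1.0)),
                           radial_k=1.0)
    from cavibind import simulate_window

    params = BrownianParams(diffusion=1.0, dt=0.005, n_steps=300_000, seed=4)
    w = simulate_window(model, None, params)
    rt = thermal_energy(model.temperature)
    edges = np.arange(-2.0, 2.01, 1.0)
    obs, _ = np.histogram(w.z[::1000], bins=edges)
    fine = np.linspace(-2, 2, 4001)
    dens = np.exp(-model.u_z(fine) / rt)
    probs = np.array([
        np.trapezoid(dens[(fine >= lo) & (fine <= hi)], fine[(fine >= lo) & (fine <= hi)])
        for lo, hi in zip(edges[:-1], edges[1:])
    ])
    probs /= probs.sum()
    np.testing.assert_allclose(obs / obs.sum(), probs, atol=0.1)
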