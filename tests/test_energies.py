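"""Pair potentials, cross-form fitting and interaction profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavibind import (
    SolventFrame,
    VdwParams,
    buffered_14_7,
    coulomb,
    fit_lj_to_14_7,
    generate_host_geometry,
    interaction_profile,
    lj_12_6,
)

params_strategy = st.tuples(st.floats(1.0, 6.0), st.floats(0.01, 2.0))


class TestLennardJones:
    def test_zero_at_sigma(self):
        p = VdwParams(r_min=3.5, epsilon=0.2)
        assert lj_12_6(p.sigma, p) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_at_r_min(self):
        p = VdwParams(r_min=3.5, epsilon=0.2)
        assert lj_12_6(3.5, p) == pytest.approx(-0.2, rel=1e-12)

    def test_decay_at_long_range(self):
        p = VdwParams(r_min=3.0, epsilon=1.0)
        assert abs(lj_12_6(30.0, p)) < 1e-4 * p.epsilon

    def test_r_zero_rejected(self):
        p = VdwParams(r_min=3.0, epsilon=1.0)
        with pytest.raises(ValueError):
            lj_12_6(0.0, p)

    def test_lorentz_berthelot_symmetry(self):
        p1 = VdwParams(r_min=3.0, epsilon=0.1)
        p2 = VdwParams(r_min=4.5, epsilon=0.4)
        r = np.linspace(2.5, 8, 20)
        np.testing.assert_allclose(lj_12_6(r, p1, p2), lj_12_6(r, p2, p1))


class TestBuffered147:
    def test_minimum_identity_at_rho_one(self):
        p = VdwParams(r_min=4.0, epsilon=0.3, form="buffered_14_7")
        assert buffered_14_7(4.0, p) == pytest.approx(-0.3, rel=1e-12)

    def test_decays_to_zero_from_below(self):
        p = VdwParams(r_min=4.0, epsilon=0.3, form="buffered_14_7")
        vals = buffered_14_7(np.array([20.0, 40.0, 80.0]), p)
        assert np.all(vals < 0)
        assert np.all(np.abs(vals) < 1e-3 * p.epsilon)
        assert np.all(np.diff(np.abs(vals)) < 0)

    def test_softer_core_than_12_6(self):
        """With equal (r_min, eps), the buffered 14-7 lies below the 12-6 on
        the repulsive approach (softer-cored form)."""
        p_lj = VdwParams(r_min=4.0, epsilon=0.3, form="lj_12_6")
        p_b = VdwParams(r_min=4.0, epsilon=0.3, form="buffered_14_7")
        for rho in (0.9, 0.8, 0.7):
            assert buffered_14_7(rho * 4.0, p_b) < lj_12_6(rho * 4.0, p_lj)

    def test_exchange_symmetry(self):
        p1 = VdwParams(r_min=3.0, epsilon=0.1, form="buffered_14_7")
        p2 = VdwParams(r_min=4.5, epsilon=0.4, form="buffered_14_7")
        r = np.linspace(2.5, 8, 20)
        np.testing.assert_allclose(buffered_14_7(r, p1, p2), buffered_14_7(r, p2, p1))


@settings(max_examples=100, derandomize=True)
@given(params=params_strategy)
def test_both_forms_equal_minus_epsilon_at_minimum(params):
    r_min, eps = params
    assert lj_12_6(r_min, VdwParams(r_min, eps)) == pytest.approx(-eps, abs=1e-8, rel=1e-8)
    assert buffered_14_7(r_min, VdwParams(r_min, eps, form="buffered_14_7")) == pytest.approx(
        -eps, abs=1e-8, rel=1e-8
    )


class TestCoulomb:
    def test_zero_charge(self):
        assert coulomb(3.0, 0.0, 1.0) == 0.0

    def test_unit_charges_near_hundred(self):
        # 332.0637/3.32 ~ -100 kcal/mol for a +1/-1 pair
        assert coulomb(3.32, 1.0, -1.0) == pytest.approx(-100.0, rel=2e-3)

    def test_inverse_distance_law(self):
        assert coulomb(6.0, 1.0, 1.0) == pytest.approx(0.5 * coulomb(3.0, 1.0, 1.0))


class TestFit:
    def test_identity_fit_recovers_12_6_target(self):
        target = VdwParams(r_min=3.8, epsilon=0.25, form="lj_12_6")
        fitted, resid = fit_lj_to_14_7(target, np.linspace(3.2, 8.0, 200))
        assert fitted.r_min == pytest.approx(3.8, abs=1e-6)
        assert fitted.epsilon == pytest.approx(0.25, abs=1e-6)
        assert resid < 1e-8

    def test_fit_to_buffered_14_7_matches_grid_search_oracle(self):
        target = VdwParams(r_min=4.0, epsilon=0.1, form="buffered_14_7")
        r = np.linspace(3.5, 9.0, 150)
        fitted, resid = fit_lj_to_14_7(target, r)
        assert abs(fitted.r_min - 4.0) < 0.1

        # dense grid-search oracle over (r_min, eps)
        y = buffered_14_7(r, target)
        best = (np.inf, None)
        for rm in np.linspace(3.6, 4.4, 81):
            for ep in np.linspace(0.05, 0.2, 76):
                sse = float(np.sum((lj_12_6(r, VdwParams(rm, ep)) - y) ** 2))
                if sse < best[0]:
                    best = (sse, (rm, ep))
        assert resid**2 <= best[0] + 1e-10
        assert fitted.r_min == pytest.approx(best[1][0], abs=0.02)

    def test_weights_at_minimum_pin_well_depth(self):
        target = VdwParams(r_min=4.0, epsilon=0.1, form="buffered_14_7")
        r = np.linspace(3.5, 9.0, 400)
        weights = np.exp(-0.5 * ((r - 4.0) / 0.05) ** 2)
        fitted, _ = fit_lj_to_14_7(target, r, weights=weights)
        assert fitted.epsilon == pytest.approx(0.1, rel=0.01)

    def test_range_must_cover_minimum(self):
        target = VdwParams(r_min=4.0, epsilon=0.1, form="buffered_14_7")
        with pytest.raises(ValueError, match="minimum"):
            fit_lj_to_14_7(target, np.linspace(5.0, 9.0, 50))


class TestInteractionProfile:
    def _frames_on_axis(self, host, z_values):
        from cavibind import cavity_center

        center = cavity_center(host)
        return [
            SolventFrame(time=float(i), ion=np.array([0.0, 0.0, z]),
                         waters=np.empty((0, 3)), host=host,
                         z_dist=float(z - center[2]))
            for i, z in enumerate(z_values)
        ]

    def _charged_host(self, charge=1.0, epsilon=0.0):
        from cavibind import HostGeometry

        atom = np.array([[0.0, 0.0, 0.0]])
        return HostGeometry(cavity_atoms=atom, all_atoms=atom,
                            charges=np.array([charge]),
                            vdw=[VdwParams(r_min=3.0, epsilon=epsilon)])

    def test_zero_parameters_zero_profile(self):
        host = self._charged_host(charge=0.0, epsilon=0.0)
        frames = self._frames_on_axis(host, np.arange(1.5, 16.0, 1.0))
        guest = VdwParams(r_min=3.0, epsilon=0.0)
        df = interaction_profile(frames, host, 0.0, guest, reference_z=15.0)
        np.testing.assert_allclose(df[["E_vdw", "E_coul", "E_total"]].to_numpy(), 0.0)

    def test_reference_bin_zero_by_construction(self):
        host = self._charged_host(charge=1.0, epsilon=0.05)
        frames = self._frames_on_axis(host, np.arange(1.5, 16.0, 1.0))
        guest = VdwParams(r_min=3.0, epsilon=0.1)
        df = interaction_profile(frames, host, -1.0, guest, reference_z=15.0)
        ref_row = df[np.isclose(df.z, 15.5)].iloc[0]
        assert ref_row.E_vdw == 0.0 and ref_row.E_coul == 0.0 and ref_row.E_total == 0.0

    def test_single_charge_matches_coulomb_closed_form(self):
        host = self._charged_host(charge=1.0, epsilon=0.0)
        z = np.arange(1.5, 16.0, 1.0)  # one frame per bin, at the bin centre
        frames = self._frames_on_axis(host, z)
        guest = VdwParams(r_min=3.0, epsilon=0.0)
        df = interaction_profile(frames, host, -1.0, guest, reference_z=15.0)
        expected = coulomb(z, -1.0, 1.0) - coulomb(15.5, -1.0, 1.0)
        np.testing.assert_allclose(df.E_coul.to_numpy(), expected, atol=1e-10)
        np.testing.assert_allclose(df.E_vdw.to_numpy(), 0.0, atol=1e-12)

    def test_components_sum_to_total(self):
        host = self._charged_host(charge=0.7, epsilon=0.08)
        frames = self._frames_on_axis(host, np.arange(2.5, 16.0, 0.5))
        guest = VdwParams(r_min=3.5, epsilon=0.12)
        df = interaction_profile(frames, host, -1.0, guest, reference_z=15.0)
        occupied = df.n_frames > 0
        np.testing.assert_allclose(
            df.E_total[occupied], (df.E_vdw + df.E_coul)[occupied], atol=1e-12
        )

    def test_missing_parameters_rejected(self, host_ring):
        frames = self._frames_on_axis(host_ring, [5.0])
        with pytest.raises(ValueError, match="charges"):
            interaction_profile(frames, host_ring, -1.0, VdwParams(3.0, 0.1))

    def test_unoccupied_reference_rejected(self):
        host = self._charged_host()
        frames = self._frames_on_axis(host, [2.0, 3.0])
        with pytest.raises(ValueError, match="reference"):
            interaction_profile(frames, host, -1.0, VdwParams(3.0, 0.1), reference_z=15.0)
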