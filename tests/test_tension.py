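"""Pressure-tensor and capillary-wave tension estimators."""

import math

import numpy as np
import pytest

from sapfilm import (
    CapillaryWaveInputs,
    DensityProfile,
    PressureTensorSeries,
    TensionEstimate,
    chunked_cw_series,
    convergence_report,
    fit_interface_width,
    gamma_capillary_wave,
    gamma_pressure_tensor,
    generate_density_profile,
    generate_pressure_tensor_series,
    molecular_diameter,
)
from sapfilm.tension import InterfaceFitError
from sapfilm.units import kbt_joules


def _series(Px, Py, Pz, h_z=60.0, n=2):
    k = len(np.atleast_1d(Px))
    return PressureTensorSeries(
        times=np.arange(k, dtype=float),
        Px=np.atleast_1d(Px), Py=np.atleast_1d(Py), Pz=np.atleast_1d(Pz),
        h_z=h_z, n_interfaces=n,
    )


class TestPressureTensor:
    def test_isotropic_box_has_zero_tension(self):
        est = gamma_pressure_tensor(_series([3.0, 1.0], [3.0, 1.0], [3.0, 1.0]))
        np.testing.assert_array_equal(est.gamma, 0.0)

    def test_dimensional_worked_example(self):
        # anisotropy of 1 MPa across a 60 nm box with two interfaces
        est = gamma_pressure_tensor(_series([0.0], [0.0], [1.0], h_z=60.0, n=2))
        assert est.gamma[0] == pytest.approx(30.0)

    def test_cumulative_mean_recovers_generating_tension(self):
        series = generate_pressure_tensor_series(40.0, 60.0, 2, 50_000, noise_sd=1.0, seed=9)
        est = gamma_pressure_tensor(series)
        se = est.gamma.std(ddof=1) / math.sqrt(len(est.gamma))
        assert abs(est.cumulative_gamma[-1] - 40.0) < 3 * se

    def test_linearity_in_pressure_components(self):
        rng = np.random.default_rng(2)
        Px, Py, Pz = rng.normal(size=(3, 50))
        base = gamma_pressure_tensor(_series(Px, Py, Pz)).gamma
        scaled = gamma_pressure_tensor(_series(3 * Px, 3 * Py, 3 * Pz)).gamma
        np.testing.assert_allclose(scaled, 3 * base, rtol=1e-12)


class TestInterfaceWidth:
    @pytest.mark.parametrize("sigma", [0.3, 0.8])
    def test_recovers_known_width(self, sigma):
        profile = generate_density_profile(sigma, (20.0, 40.0), 60.0, 300)
        assert fit_interface_width(profile) == pytest.approx(sigma, rel=0.01)

    def test_amplitude_rescaling_leaves_width_unchanged(self):
        a = generate_density_profile(0.4, (20.0, 40.0), 60.0, 300, bulk_density=1.0)
        b = generate_density_profile(0.4, (20.0, 40.0), 60.0, 300, bulk_density=7.0)
        assert fit_interface_width(a) == pytest.approx(fit_interface_width(b), rel=1e-6)

    def test_independent_mode_reports_both_interfaces(self):
        profile = generate_density_profile(0.5, (20.0, 40.0), 60.0, 300)
        sigma, info = fit_interface_width(profile, independent=True, full_output=True)
        assert info["sigma_lo"] == pytest.approx(info["sigma_hi"], rel=0.02)
        assert sigma == pytest.approx(0.5, rel=0.01)

    def test_flat_profile_is_rejected(self):
        flat = DensityProfile(
            z_centers=np.linspace(0.1, 59.9, 300), density=np.ones(300), h_z=60.0
        )
        with pytest.raises(InterfaceFitError):
            fit_interface_width(flat)


class TestMolecularDiameter:
    def test_standard_slab_value(self):
        # 2*sqrt(324 / (pi*276)) = 1.2226 nm, averaged with the water vdW 0.28
        assert molecular_diameter(18.0, 276, 0.28) == pytest.approx(0.75128, abs=1e-4)

    def test_mean_of_equal_diameters_is_identity(self):
        # pick the lipid count so the head-group disc equals the water diameter
        h_xy, w = 10.0, 0.28
        n = round(4 * h_xy**2 / (math.pi * w**2))
        d = 2 * math.sqrt(h_xy**2 / (math.pi * n))
        assert molecular_diameter(h_xy, n, w) == pytest.approx(d, rel=1e-3)

    def test_doubling_box_width_doubles_head_diameter(self):
        l1 = molecular_diameter(18.0, 276, 0.0)
        l2 = molecular_diameter(36.0, 276, 0.0)
        assert l2 == pytest.approx(2 * l1)


class TestCapillaryWave:
    def test_worked_example(self):
        gamma = gamma_capillary_wave(CapillaryWaveInputs(sigma=0.3, l=0.75, h_z=60.0))
        assert gamma == pytest.approx(31.88, abs=0.05)

    def test_inverse_square_width_scaling(self):
        g1 = gamma_capillary_wave(CapillaryWaveInputs(sigma=0.3, l=0.75, h_z=60.0))
        g2 = gamma_capillary_wave(CapillaryWaveInputs(sigma=0.6, l=0.75, h_z=60.0))
        assert g2 == pytest.approx(g1 / 4)

    def test_log_term_normalization(self):
        l = 0.7
        gamma = gamma_capillary_wave(CapillaryWaveInputs(sigma=0.4, l=l, h_z=l * math.e))
        expected = kbt_joules(298.0) / (2 * math.pi * (0.4e-9) ** 2) * 1e3
        assert gamma == pytest.approx(expected, rel=1e-12)

    def test_box_shorter_than_molecule_rejected(self):
        with pytest.raises(ValueError):
            CapillaryWaveInputs(sigma=0.3, l=2.0, h_z=1.0)


def _stationary_profiles(n_frames, sigma=0.3, h_z=60.0, noise=0.01, seed0=100):
    times = np.arange(n_frames) * 100.0
    profiles = [
        generate_density_profile(
            sigma, (20.0, 40.0), h_z, 300, seed=seed0 + i, noise_sd=noise
        )
        for i in range(n_frames)
    ]
    return times, profiles


class TestChunkedSeries:
    def test_stationary_chunks_agree(self):
        times, profiles = _stationary_profiles(30)
        est = chunked_cw_series(times, profiles, 18.0, 276, chunk_length=500.0)
        assert est.chunk_length == 500.0
        assert np.ptp(est.gamma) < 0.02 * est.gamma.mean()

    def test_chunk_value_matches_closed_form(self):
        times, profiles = _stationary_profiles(10, noise=0.0)
        est = chunked_cw_series(times, profiles, 18.0, 276, chunk_length=500.0)
        l = molecular_diameter(18.0, 276)
        expected = gamma_capillary_wave(CapillaryWaveInputs(sigma=0.3, l=l, h_z=60.0))
        np.testing.assert_allclose(est.gamma, expected, rtol=1e-3)

    def test_short_trajectory_rejected(self):
        times, profiles = _stationary_profiles(3)
        with pytest.raises(ValueError):
            chunked_cw_series(times[:3], profiles[:3], 18.0, 276, chunk_length=10_000.0)


class TestConvergenceReport:
    def _pt(self, gamma, n=50):
        return TensionEstimate(
            method="pressure_tensor",
            times=np.arange(n) * 100.0,
            gamma=np.full(n, gamma),
            cumulative_gamma=np.full(n, gamma),
        )

    def _cw(self, gammas, sd=1.0):
        n = len(gammas)
        return TensionEstimate(
            method="capillary_wave",
            times=np.arange(n) * 500.0 + 250.0,
            gamma=np.asarray(gammas, dtype=float),
            chunk_length=500.0,
            gamma_top=np.asarray(gammas, dtype=float),
            gamma_bottom=np.asarray(gammas, dtype=float),
            gamma_sd=np.full(n, sd),
        )

    def test_identical_series_converge_immediately(self):
        report = convergence_report(self._pt(40.0), self._cw([40.0] * 9))
        assert report["first_agreement_time"] == pytest.approx(250.0)
        assert report["top_bottom_rule_ok"]

    def test_injected_interface_divergence_is_flagged(self):
        cw = self._cw([40.0] * 9, sd=0.5)
        cw.gamma_top = cw.gamma_top + 5.0  # one monolayer drifts away
        report = convergence_report(self._pt(40.0), cw)
        assert not report["top_bottom_rule_ok"]
        assert len(report["top_bottom_rule_violations"]) == 9

    def test_disjoint_time_ranges_rejected(self):
        pt = self._pt(40.0, n=5)  # covers 0..400 ps
        cw = self._cw([40.0] * 4)
        cw.times = cw.times + 10_000.0
        with pytest.raises(ValueError):
            convergence_report(pt, cw)

    def test_equilibrium_synthetic_run_reaches_agreement(self):
        series = generate_pressure_tensor_series(
            31.9, 60.0, 2, 5000, noise_sd=1.0, seed=4, dt=1.0
        )
        pt = gamma_pressure_tensor(series)
        times, profiles = _stationary_profiles(10, sigma=0.3, noise=0.005)
        cw = chunked_cw_series(times, profiles, 18.0, 276, chunk_length=500.0)
        report = convergence_report(pt, cw, tolerance=2.0)
        assert report["first_agreement_time"] is not None
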