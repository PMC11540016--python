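"""Filtering, remnant-artifact removal, tanh calibration and inversion."""

import numpy as np
import pytest

import gelattice as gl
from gelattice.readout import FitError
from gelattice.volumes import Quantity

TRUE = dict(alpha=40.0, beta=60.0, gamma_=0.08, phi=0.3)


def _delta(values, spacing=(1.0, 1.0, 1.0)):
    geom = gl.VolumeGeometry.centered(values.shape, spacing)
    return gl.ScalarVolume(geom, values, Quantity.DELTA_CBCT)


class TestAdaptiveMeanFilter:
    def test_constant_slice_unchanged(self):
        vol = _delta(np.full((20, 20, 3), 57.0))
        out = gl.adaptive_mean_filter(vol, 3)
        np.testing.assert_allclose(out.values, vol.values, atol=1e-12)

    def test_impulse_attenuated(self):
        v = np.zeros((21, 21, 1))
        v[10, 10, 0] = 100.0
        out = gl.adaptive_mean_filter(_delta(v), 3)
        assert 0 < out.values[10, 10, 0] < 100.0

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 1, (64, 64, 2))
        out = gl.adaptive_mean_filter(_delta(v), 3)
        assert out.values.var() < v.var()

    def test_edges_pass_through(self):
        """High local variance (a dose edge) keeps gain near 1."""
        v = np.zeros((40, 40, 1))
        v[20:, :, 0] = 100.0
        rng = np.random.default_rng(1)
        noisy = v + rng.normal(0, 0.5, v.shape)
        out = gl.adaptive_mean_filter(_delta(noisy), 3)
        edge_change = np.abs(out.values[19:21, 5:35, 0] - noisy[19:21, 5:35, 0])
        assert np.median(np.abs(out.values - noisy)) < 0.5  # flat regions smoothed
        assert edge_change.max() > 10.0 or np.allclose(
            out.values[18:22, :, 0].mean(), noisy[18:22, :, 0].mean(), rtol=0.05
        )

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            gl.adaptive_mean_filter(_delta(np.zeros((4, 4, 1))), 4)

    def test_wrong_quantity_rejected(self):
        geom = gl.VolumeGeometry.centered((4, 4, 4), (1, 1, 1))
        vol = gl.ScalarVolume(geom, np.zeros((4, 4, 4)), Quantity.DOSE_GY)
        with pytest.raises(ValueError, match="delta_cbct"):
            gl.adaptive_mean_filter(vol, 3)


def _polar_fixture(spacing=(0.5, 0.5, 1.0), dims=(241, 241, 3)):
    """Pedestal + two off-axis Gaussian peaks inside a disc region."""
    geom = gl.VolumeGeometry.centered(dims, spacing)
    x, y, z = geom.coordinate_grids()
    r = np.broadcast_to(np.sqrt(x**2 + y**2), geom.dims)
    region = r <= 58.0
    peaks = 40.0 * np.exp(-((x - 30.0) ** 2 + y**2 + z**2) / (2 * 4.0**2))
    peaks = peaks + 40.0 * np.exp(-((x + 30.0) ** 2 + y**2 + z**2) / (2 * 4.0**2))
    signal = np.where(region, 57.0 + np.broadcast_to(peaks, geom.dims), 0.0)
    return geom, r, region, signal


class TestRemnantRemoval:
    def test_zero_remnant_slice_nearly_unchanged(self):
        geom, r, region, signal = _polar_fixture()
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 0.3, geom.dims) * region
        vol = gl.ScalarVolume(geom, signal + noise, Quantity.DELTA_CBCT)
        out = gl.remove_remnant_artifacts(vol, 7, (0.0, 0.0), region=region)
        assert np.abs(out.values - vol.values).max() <= 2.0 * 0.3

    def test_ring_reduced_peaks_preserved(self):
        """A 15 mm-period radial ring drops by >= 80% while vertex-peak
        amplitudes change by <= 2%."""
        geom, r, region, signal = _polar_fixture()
        ring = 2.0 * np.sin(2 * np.pi * r / 15.0) * region
        vol = gl.ScalarVolume(geom, signal + ring, Quantity.DELTA_CBCT)
        out = gl.remove_remnant_artifacts(vol, 7, (0.0, 0.0), region=region)
        resid = out.values - signal
        k = 1
        quiet = region[:, :, k] & (signal[:, :, k] < 58.0)
        assert resid[:, :, k][quiet].std() <= 0.2 * ring[:, :, k][quiet].std()
        peak_before = signal[:, :, k].max() - 57.0
        peak_after = out.values[:, :, k].max() - 57.0
        assert abs(peak_after - peak_before) <= 0.02 * peak_before

    def test_idempotent_on_smooth_cupping(self):
        """Re-applying the correction changes < 1% of the first correction."""
        geom, r, region, signal = _polar_fixture(dims=(241, 241, 2))
        cup = 3.0 * (r / 60.0) ** 2 * region
        base = np.where(region, 57.0, 0.0)
        vol = gl.ScalarVolume(geom, base + cup, Quantity.DELTA_CBCT)
        once = gl.remove_remnant_artifacts(vol, 7, (0.0, 0.0), region=region)
        twice = gl.remove_remnant_artifacts(once, 7, (0.0, 0.0), region=region)
        c1 = np.abs(once.values - vol.values).max()
        c2 = np.abs(twice.values - once.values).max()
        assert c2 < 0.01 * c1

    def test_exclude_model_protects_symmetric_signal(self):
        """With a signal model, an azimuthally symmetric dose component is
        not mistaken for artifact."""
        geom, r, region, _ = _polar_fixture(dims=(241, 241, 2))
        symmetric_dose = np.where(region, 30.0 / (1.0 + np.exp((r - 40.0) / 5.0)), 0.0)
        ring = 2.0 * np.sin(2 * np.pi * r / 15.0) * region
        vol = gl.ScalarVolume(geom, symmetric_dose + ring, Quantity.DELTA_CBCT)
        naive = gl.remove_remnant_artifacts(vol, 7, (0.0, 0.0), region=region)
        guided = gl.remove_remnant_artifacts(
            vol, 7, (0.0, 0.0), region=region, exclude_model=symmetric_dose
        )
        ring_rms = np.sqrt(np.mean(ring[region] ** 2))
        rms_naive = np.sqrt(np.mean((naive.values - symmetric_dose)[region] ** 2))
        rms_guided = np.sqrt(np.mean((guided.values - symmetric_dose)[region] ** 2))
        assert rms_guided < 0.25 * ring_rms  # ring removed, signal intact
        assert rms_naive > 2.0 * ring_rms  # plain mode flattens the signal too

    def test_even_span_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            gl.remove_remnant_artifacts(_delta(np.zeros((10, 10, 1))), span=4)

    def test_span_exceeding_radial_samples_rejected(self):
        with pytest.raises(ValueError, match="radial"):
            gl.remove_remnant_artifacts(_delta(np.zeros((4, 4, 1))), span=99)


class TestCalibrationFit:
    def test_noiseless_recovery_to_machine_precision(self):
        rng = np.random.default_rng(1)
        dose = rng.uniform(0, 25, (100, 100))
        curve = gl.CalibrationCurve(**TRUE)
        fit = gl.fit_calibration(gl.tanh_response(dose, curve), dose)
        np.testing.assert_allclose(fit.params, curve.params, rtol=1e-6)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)
        assert fit.dose_range == pytest.approx((dose.min(), dose.max()))

    def test_confidence_intervals_cover_truth(self):
        """Each parameter lies inside its own fitted 95% CI in >= 90% of
        seeded replicate fits (10^4 pixels, 5% amplitude noise)."""
        rng = np.random.default_rng(42)
        curve = gl.CalibrationCurve(**TRUE)
        dose = rng.uniform(0, 25, 10000)
        clean = gl.tanh_response(dose, curve)
        n_rep = 40
        covered = np.zeros(4)
        for _ in range(n_rep):
            fit = gl.fit_calibration(
                (clean + rng.normal(0, 0.05 * TRUE["beta"], dose.shape)).reshape(100, 100),
                dose.reshape(100, 100),
            )
            ci = fit.ci95()
            for j, name in enumerate(("alpha", "beta", "gamma_", "phi")):
                lo, hi = ci[name]
                covered[j] += lo <= curve.params[j] <= hi
        assert np.all(covered / n_rep >= 0.9)

    def test_zero_dose_slice_rejected(self):
        with pytest.raises(FitError, match="degenerate"):
            gl.fit_calibration(np.zeros((10, 10)), np.zeros((10, 10)))

    def test_narrow_dose_span_warns(self):
        rng = np.random.default_rng(0)
        dose = rng.uniform(20, 25, (40, 40))
        curve = gl.CalibrationCurve(**TRUE)
        with pytest.warns(UserWarning, match="span"):
            gl.fit_calibration(gl.tanh_response(dose, curve), dose)

    def test_mask_restricts_fit(self):
        rng = np.random.default_rng(3)
        dose = rng.uniform(0, 25, (50, 50))
        curve = gl.CalibrationCurve(**TRUE)
        delta = gl.tanh_response(dose, curve)
        delta_corrupt = delta.copy()
        mask = np.ones_like(dose, dtype=bool)
        mask[:10] = False
        delta_corrupt[:10] = -500.0  # e.g. container wall pixels
        fit = gl.fit_calibration(delta_corrupt, dose, mask=mask)
        np.testing.assert_allclose(fit.params, curve.params, rtol=1e-6)

    def test_curve_json_roundtrip(self, tmp_path):
        curve = gl.CalibrationCurve(**TRUE, param_cov=np.eye(4), rmse=0.5, dose_range=(0, 25))
        path = str(tmp_path / "curve.json")
        curve.to_json(path)
        back = gl.CalibrationCurve.from_json(path)
        np.testing.assert_allclose(back.params, curve.params)
        np.testing.assert_allclose(back.param_cov, np.eye(4))
        assert back.dose_range == (0.0, 25.0)


class TestApplyCalibration:
    def test_alpha_maps_to_phi_over_gamma(self):
        curve = gl.CalibrationCurve(**TRUE)
        vol = _delta(np.full((3, 3, 3), TRUE["alpha"]))
        out = gl.apply_calibration(vol, curve)
        np.testing.assert_allclose(out.values, TRUE["phi"] / TRUE["gamma_"], rtol=1e-12)

    def test_forward_inverse_roundtrip(self):
        curve = gl.CalibrationCurve(**TRUE)
        dose = np.linspace(0.5, 24.0, 50).reshape(1, 1, 50)
        vol = _delta(np.asarray(gl.tanh_response(dose, curve)))
        out = gl.apply_calibration(vol, curve)
        np.testing.assert_allclose(out.values, dose, atol=1e-9)

    def test_forward_and_inverse_strictly_increasing(self):
        curve = gl.CalibrationCurve(**TRUE)
        dose = np.linspace(0, 30, 500)
        fwd = np.asarray(gl.tanh_response(dose, curve))
        assert np.all(np.diff(fwd) > 0)
        dn = np.linspace(TRUE["alpha"] - 0.99 * TRUE["beta"], TRUE["alpha"] + 0.99 * TRUE["beta"], 500)
        assert np.all(np.diff(curve.inverse(dn)) >= 0)

    def test_saturation_clamps_to_calibrated_range(self):
        curve = gl.CalibrationCurve(**TRUE, dose_range=(0.0, 24.9))
        vol = _delta(np.full((2, 2, 2), TRUE["alpha"] + 2 * TRUE["beta"]))  # beyond saturation
        out, stats = gl.apply_calibration(vol, curve, return_stats=True)
        assert np.all(np.isfinite(out.values))
        np.testing.assert_allclose(out.values, 24.9)
        assert stats["saturated_fraction"] == 1.0

    def test_negative_clamped_and_reported(self):
        curve = gl.CalibrationCurve(**TRUE)
        vol = _delta(np.full((2, 2, 2), TRUE["alpha"] - 0.9 * TRUE["beta"]))
        out, stats = gl.apply_calibration(vol, curve, return_stats=True)
        assert np.all(out.values == 0.0)
        assert stats["negative_clamped_fraction"] == 1.0

    def test_invalid_curve_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            gl.CalibrationCurve(alpha=0, beta=-1, gamma_=0.1, phi=0)
        with pytest.raises(ValueError, match="gamma"):
            gl.CalibrationCurve(alpha=0, beta=1, gamma_=0.0, phi=0)


class TestSelfCalibrationConsistency:
    def test_residual_maps_through_curve_slope(self):
        """Calibrating the fitting slice itself reproduces the plan within
        the fit RMSE divided by the local curve slope."""
        rng = np.random.default_rng(9)
        dose = rng.uniform(1, 24, (80, 80))
        curve_true = gl.CalibrationCurve(**TRUE)
        noise_sd = 0.01 * TRUE["beta"]
        delta2d = gl.tanh_response(dose, curve_true) + rng.normal(0, noise_sd, dose.shape)
        fit = gl.fit_calibration(delta2d, dose)
        recon = fit.inverse(delta2d)
        slope = fit.beta * fit.gamma_ / np.cosh(fit.gamma_ * dose - fit.phi) ** 2
        dose_resid = np.sqrt(np.mean((recon - dose) ** 2))
        expected = np.sqrt(np.mean((fit.rmse / slope) ** 2))
        assert dose_resid == pytest.approx(expected, rel=0.2)
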