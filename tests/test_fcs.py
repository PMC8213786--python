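"""FCS tests: diffusion model closed forms, fit round trips, calibration,
background correction and QC filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circanuc.fcs import (
    FCS_PRESETS,
    FocalVolume,
    calibrate_focal_volume,
    cell_mean_concentrations,
    correct_concentration,
    fit_autocorrelation,
    generate_fcs_cohort,
    generate_fcs_curve,
    model_autocorrelation,
    qc_and_floor,
)


class TestModel:
    def test_small_lag_limit_is_inverse_n(self):
        g = model_autocorrelation(1e-12, N=8.0, tau_D=1e-3, kappa=5.0)
        assert g == pytest.approx(1 / 8.0, rel=1e-6)

    def test_strictly_decreasing(self):
        tau = np.geomspace(1e-6, 10, 200)
        g = model_autocorrelation(tau, N=5.0, tau_D=2e-3, kappa=5.0)
        assert np.all(np.diff(g) < 0)

    def test_value_at_diffusion_time(self):
        kappa = 5.0
        g = model_autocorrelation(1e-3, N=2.0, tau_D=1e-3, kappa=kappa)
        assert g == pytest.approx(0.5 * 0.5 / np.sqrt(1 + 1 / kappa**2))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            model_autocorrelation(-1e-3, N=1.0, tau_D=1e-3, kappa=5.0)
        with pytest.raises(ValueError):
            model_autocorrelation(1e-3, N=0.0, tau_D=1e-3, kappa=5.0)


class TestGenerateAndFit:
    def test_noiseless_round_trip_1e6(self):
        curve = generate_fcs_curve(N=10.0, tau_D=1e-3, kappa=5.0)
        fit = fit_autocorrelation(curve, kappa=5.0)
        assert fit.N == pytest.approx(10.0, rel=1e-6)
        assert fit.tau_D == pytest.approx(1e-3, rel=1e-6)

    def test_intercept_is_inverse_n(self):
        curve = generate_fcs_curve(N=10.0, tau_D=1e-3)
        fit = fit_autocorrelation(curve, kappa=5.0)
        assert 1.0 / fit.N == pytest.approx(0.1, rel=1e-6)

    def test_same_seed_identical_curves(self):
        a = generate_fcs_curve(N=3.0, tau_D=1e-3, noise_sd=0.05, seed=4)
        b = generate_fcs_curve(N=3.0, tau_D=1e-3, noise_sd=0.05, seed=4)
        assert np.array_equal(a.G, b.G)

    def test_noise_sd_scales_residuals(self):
        clean = generate_fcs_curve(N=3.0, tau_D=1e-3, seed=4)
        low = generate_fcs_curve(N=3.0, tau_D=1e-3, noise_sd=0.02, seed=4)
        high = generate_fcs_curve(N=3.0, tau_D=1e-3, noise_sd=0.04, seed=4)
        assert np.allclose(high.G - clean.G, 2 * (low.G - clean.G), rtol=1e-9)

    def test_multiplicative_noise_bias_below_2pct(self):
        fitted = []
        rng = np.random.default_rng(8)
        for _ in range(100):
            curve = generate_fcs_curve(N=10.0, tau_D=1e-3, noise_sd=0.05, seed=rng)
            fit = fit_autocorrelation(curve, kappa=5.0)
            if fit.converged:
                fitted.append(fit.N)
        assert abs(np.mean(fitted) - 10.0) / 10.0 < 0.02


class TestCalibration:
    def test_reference_arithmetic(self):
        curve = generate_fcs_curve(N=5.0, tau_D=25e-6, kappa=5.0, lag_range=(1e-7, 1e-2))
        vol = calibrate_focal_volume(curve, D_ref=400.0, kappa=5.0)
        assert vol.w0 == pytest.approx(0.2, rel=1e-6)
        assert vol.v_eff == pytest.approx(np.pi**1.5 * 0.2**3 * 5.0, rel=1e-6)

    def test_doubling_d_ref_scales_w0_by_sqrt2(self):
        curve = generate_fcs_curve(N=5.0, tau_D=25e-6, kappa=5.0, lag_range=(1e-7, 1e-2))
        a = calibrate_focal_volume(curve, D_ref=400.0)
        b = calibrate_focal_volume(curve, D_ref=800.0)
        assert b.w0 / a.w0 == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_round_trip_known_w0(self):
        w0, kappa, D = 0.25, 5.0, 2.3
        curve = generate_fcs_curve(N=2.0, tau_D=w0**2 / (4 * D), kappa=kappa, lag_range=(1e-6, 60.0))
        vol = calibrate_focal_volume(curve, D_ref=D, kappa=kappa)
        assert vol.w0 == pytest.approx(w0, rel=1e-6)


class TestBackgroundCorrection:
    def test_identity_without_background(self):
        assert correct_concentration(3.0, 1e4, 0.0, fluorescent_fraction=1.0) == pytest.approx(3.0)

    def test_quarter_factor_at_half_background(self):
        c = correct_concentration(1.0, 2000.0, 1000.0, fluorescent_fraction=1.0)
        assert c == pytest.approx(0.25)

    def test_arithmetic_example(self):
        c = correct_concentration(1.0, 10_000.0, 2000.0, fluorescent_fraction=0.6)
        assert c == pytest.approx(0.64 / 0.6)

    def test_below_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            correct_concentration(1.0, 900.0, 1000.0)

    @given(fm=st.floats(1100, 1e6), bump=st.floats(1, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_correction_factor_monotone_in_signal(self, fm, bump):
        """The background correction factor lies in (0, 1] and grows with the
        measured count rate at fixed background."""
        f_bg = 1000.0
        a = correct_concentration(1.0, fm, f_bg, fluorescent_fraction=1.0)
        b = correct_concentration(1.0, fm + bump, f_bg, fluorescent_fraction=1.0)
        assert 0 < a <= 1.0
        assert b > a


class TestQC:
    def _fits(self, n=6):
        vol = FocalVolume(w0=0.2)
        curves = [generate_fcs_curve(N=5.0, tau_D=1e-3, F_m=1.5e4, F_BG=1000.0, seed=i)
                  for i in range(n)]
        return [fit_autocorrelation(c, kappa=5.0, volume=vol) for c in curves]

    def test_clean_cohort_passes_unchanged(self):
        fits = self._fits()
        kept = qc_and_floor(fits, floor=0.11)
        assert len(kept) == len(fits)
        assert not any(f.floored for f in kept)

    def test_below_background_entry_floored_at_0_11(self):
        fits = self._fits()
        vol = FocalVolume(w0=0.2)
        dim = fit_autocorrelation(
            generate_fcs_curve(N=5.0, tau_D=1e-3, F_m=800.0, F_BG=1000.0), kappa=5.0, volume=vol)
        kept = qc_and_floor(fits + [dim], floor=0.11)
        floored = [f for f in kept if f.floored]
        assert len(floored) == 1
        assert floored[0].c_final == pytest.approx(0.11)

    def test_low_cpm_outliers_removed_exactly(self):
        fits = self._fits(8)
        vol = FocalVolume(w0=0.2)
        # same N but 100x dimmer count rate -> cpm far below the cohort
        outlier = fit_autocorrelation(
            generate_fcs_curve(N=5.0, tau_D=1e-3, F_m=150.0, F_BG=10.0), kappa=5.0, volume=vol)
        kept = qc_and_floor(fits + [outlier], floor=0.11)
        assert len(kept) == len(fits)
        assert all(f.cpm > 1000 for f in kept)

    def test_auto_floor_is_10th_percentile(self):
        vol = FocalVolume(w0=0.2)
        curves = [generate_fcs_curve(N=float(n), tau_D=1e-3, F_m=3000.0 * n, F_BG=100.0)
                  for n in range(1, 11)]
        fits = [fit_autocorrelation(c, kappa=5.0, volume=vol) for c in curves]
        dim = fit_autocorrelation(
            generate_fcs_curve(N=5.0, tau_D=1e-3, F_m=80.0, F_BG=100.0), kappa=5.0, volume=vol)
        kept = qc_and_floor(fits + [dim], floor="auto")
        finals = np.array([f.c_final for f in kept if not f.floored])
        floored = [f for f in kept if f.floored]
        assert len(floored) == 1
        assert floored[0].c_final == pytest.approx(np.percentile(finals, 10))

    def test_cell_aggregation_is_arithmetic_mean(self):
        fits = self._fits(10)
        kept = qc_and_floor(fits, floor=0.11)
        per_cell = cell_mean_concentrations(kept, areas_per_cell=5)
        values = np.array([f.c_final for f in kept])
        assert per_cell[0] == pytest.approx(values[:5].mean())
        assert per_cell[1] == pytest.approx(values[5:].mean())


def test_cry1_preset_cohort_recovers_concentration_and_d():
    """End to end: calibrate, generate the CRY1-channel cohort with its
    consistent forward background model, fit and correct; the cohort mean
    recovers the preset concentration and the fitted D its diffusion
    coefficient."""
    ref = generate_fcs_curve(N=5.0, tau_D=25e-6, kappa=5.0, lag_range=(1e-7, 1e-2))
    vol = calibrate_focal_volume(ref, D_ref=400.0, kappa=5.0)
    preset = FCS_PRESETS["CRY1-mClover3"]
    curves = generate_fcs_cohort(preset, vol, n=10, seed=3)
    fits = [fit_autocorrelation(c, kappa=vol.kappa, volume=vol) for c in curves]
    kept = qc_and_floor(fits, floor=0.11, fluorescent_fraction=preset.fluorescent_fraction)
    c_mean = np.mean([f.c_final for f in kept])
    d_mean = np.mean([f.D for f in kept])
    assert c_mean == pytest.approx(preset.concentration, rel=0.10)
    assert d_mean == pytest.approx(preset.D, rel=0.05)
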