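"""Preprocessing: acquisition arithmetic, apodization, zero-fill, FT,
phasing, baseline, chemical-shift calibration."""

from __future__ import annotations

import math

import numpy as np
import pytest

from plasmanmr.preprocess import (
    CalibrationError,
    acquisition_time,
    apodize,
    baseline_correct,
    calibrate_shift,
    cpmg_mixing_time,
    fourier_transform,
    phase_correct,
    preprocess,
    zero_fill,
)
from plasmanmr.simulate import FID, AcquisitionParams, SimConfig, simulate_cohort

from conftest import synth_fid, synth_spectrum


class TestAcquisitionArithmetic:
    @pytest.mark.parametrize("n,sw,freq,expected", [
        (16384, 16, 600, 0.853),   # the instrument's stated setting
        (0, 16, 600, 0.0),
        (19200, 16, 600, 1.000),
    ])
    def test_acquisition_time(self, n, sw, freq, expected):
        assert acquisition_time(n, sw, freq) == pytest.approx(expected, abs=5e-4)

    def test_acquisition_time_rounds_to_085(self):
        assert round(acquisition_time(16384, 16, 600), 2) == 0.85

    def test_acquisition_time_invalid(self):
        with pytest.raises(ValueError):
            acquisition_time(-1, 16, 600)
        with pytest.raises(ValueError):
            acquisition_time(16384, 0, 600)

    @pytest.mark.parametrize("pulses,rate,expected", [
        (100, 3600, 55.56),  # rotor-synchronized train, two periods per echo
        (0, 3600, 0.0),
        (18, 3600, 10.00),
    ])
    def test_cpmg_mixing_time(self, pulses, rate, expected):
        assert cpmg_mixing_time(pulses, rate) == pytest.approx(expected, abs=5e-3)

    def test_cpmg_invalid(self):
        with pytest.raises(ValueError):
            cpmg_mixing_time(100, 0)


class TestApodize:
    def test_zero_lb_is_identity(self, acq_small):
        fid = synth_fid([(3.0, 1.0, 4.0)], acq_small)
        out = apodize(fid, 0.0)
        np.testing.assert_array_equal(out.points, fid.points)

    def test_first_point_unchanged(self, acq_small):
        fid = synth_fid([(3.0, 1.0, 4.0)], acq_small)
        out = apodize(fid, 25.0)
        assert out.points[0] == fid.points[0]

    def test_elementwise_weights(self):
        acq = AcquisitionParams(spectral_width_ppm=5.0 / 600.0,
                                n_points_td=4)  # dwell 0.1 s
        fid = FID(points=np.ones(4, dtype=complex), dwell_s=0.1, acquisition=acq)
        out = apodize(fid, 1.0)
        expected = np.exp(-math.pi * 1.0 * np.array([0.0, 0.1, 0.2, 0.3]))
        np.testing.assert_allclose(out.points.real, expected, rtol=1e-12)


class TestZeroFill:
    def test_16k_doubles_to_32k(self):
        acq = AcquisitionParams()
        fid = FID(np.ones(16384, dtype=complex), acq.dwell_s, acq)
        assert zero_fill(fid, 2).points.size == 32768

    def test_factor_one_is_identity(self, acq_small):
        fid = synth_fid([(3.0, 1.0, 4.0)], acq_small)
        np.testing.assert_array_equal(zero_fill(fid, 1).points, fid.points)

    def test_sum_and_prefix_preserved(self, acq_small):
        fid = synth_fid([(3.0, 1.0, 4.0)], acq_small)
        out = zero_fill(fid, 2)
        np.testing.assert_array_equal(out.points[:fid.points.size], fid.points)
        assert out.points[fid.points.size:].sum() == 0
        assert out.points.sum() == pytest.approx(fid.points.sum(), rel=1e-12)

    def test_invalid_factor(self, acq_small):
        fid = synth_fid([(3.0, 1.0, 4.0)], acq_small)
        with pytest.raises(ValueError):
            zero_fill(fid, 0)


class TestFourierTransform:
    def test_zero_fid_gives_zero_spectrum(self, acq_small):
        fid = FID(np.zeros(512, dtype=complex), acq_small.dwell_s, acq_small)
        spec = fourier_transform(fid)
        assert np.all(spec.intensity == 0)

    def test_peak_lands_at_its_ppm(self, acq_small):
        spec = synth_spectrum([(3.0, 1.0, 6.0)], acq_small, lb_hz=0.0)
        apex = spec.ppm[int(np.argmax(spec.intensity))]
        assert abs(apex - 3.0) <= spec.ppm_spacing

    def test_axis_is_strictly_decreasing(self, acq_small):
        spec = synth_spectrum([(3.0, 1.0, 6.0)], acq_small)
        assert np.all(np.diff(spec.ppm) < 0)

    def test_parseval(self, acq_small):
        fid = synth_fid([(3.0, 1.0, 6.0), (1.2, 0.5, 8.0)], acq_small,
                        noise_sd=0.1, seed=4)
        spec = fourier_transform(fid)
        power_t = np.sum(np.abs(fid.points) ** 2)
        power_f = np.sum(np.abs(spec.complex_data) ** 2) / fid.points.size
        assert power_f == pytest.approx(power_t, rel=1e-9)


class TestPhaseCorrect:
    def test_manual_identity(self, acq_small):
        spec = synth_spectrum([(3.0, 1.0, 6.0)], acq_small)
        out = phase_correct(spec, auto=False, phi0_deg=0.0, phi1_deg=0.0)
        np.testing.assert_allclose(out.intensity, spec.intensity, rtol=1e-12)

    def test_auto_on_phased_spectrum_is_near_zero(self, acq_small):
        # peaks spread across the digitized band pin both phase orders
        lines = [(p, 1.0, 6.0) for p in (-8.0, -3.0, 2.0, 7.0, 12.0, 17.0)]
        spec = synth_spectrum(lines, acq_small, lb_hz=1.0)
        out = phase_correct(spec, auto=True)
        entry = out.processing_log[-1]
        phi0 = float(entry.split("phi0_deg=")[1].split(",")[0])
        phi1 = float(entry.split("phi1_deg=")[1].split(")")[0])
        assert abs(phi0) < 1.0 and abs(phi1) < 1.0

    @pytest.mark.parametrize("phi0,phi1", [(25.0, 0.0), (-40.0, 30.0), (160.0, -20.0)])
    def test_auto_reduces_negative_fraction(self, acq_small, phi0, phi1):
        lines = [(p, 1.0, 6.0) for p in (-8.0, -3.0, 2.0, 7.0, 12.0, 17.0)]
        fid = synth_fid(lines, acq_small, phi0_deg=phi0, phi1_deg=phi1)
        distorted = fourier_transform(zero_fill(apodize(fid, 1.0), 2))

        def negfrac(s):
            return float((np.minimum(s.intensity, 0) ** 2).sum()
                         / (s.intensity ** 2).sum())

        clean = synth_spectrum(lines, acq_small, lb_hz=1.0)
        corrected = phase_correct(distorted, auto=True)
        assert negfrac(corrected) < negfrac(clean) + 0.01


class TestBaselineCorrect:
    def test_null_case_changes_little(self, acq_small):
        spec = synth_spectrum([(3.0, 1.0, 6.0)], acq_small)
        out = baseline_correct(spec)
        peak = spec.intensity.max()
        assert np.abs(out.intensity - spec.intensity).max() < 0.01 * peak

    def test_quadratic_drift_removed(self, acq_small):
        spec = synth_spectrum([(3.0, 1.0, 6.0), (1.5, 0.6, 6.0)], acq_small)
        peak = spec.intensity.max()
        x = np.linspace(-1, 1, spec.ppm.size)
        drift = 0.05 * peak * (0.3 + x + x ** 2)
        spec.intensity = spec.intensity + drift
        out = baseline_correct(spec)
        quiet = (spec.ppm > 7.0) & (spec.ppm < 15.0)  # peak-free window
        assert np.abs(out.intensity[quiet]).max() < 0.02 * peak

    def test_peak_integrals_survive(self, acq_small):
        clean = synth_spectrum([(3.0, 1.0, 6.0)], acq_small)
        drifted = synth_spectrum([(3.0, 1.0, 6.0)], acq_small)
        x = np.linspace(-1, 1, clean.ppm.size)
        drifted.intensity = drifted.intensity + 0.05 * clean.intensity.max() * (x ** 2 + 0.5)
        out = baseline_correct(drifted)
        win = clean.window(2.9, 3.1)
        truth = clean.intensity[win].sum()
        assert out.intensity[win].sum() == pytest.approx(truth, rel=0.05)


class TestCalibrateShift:
    def lactate_lines(self, offset=0.0):
        j_ppm = 7.0 / 600.0
        return [(1.32 + offset, 1.0, 4.0), (1.32 + j_ppm + offset, 1.0, 4.0),
                (3.0 + offset, 0.8, 4.0)]

    @pytest.mark.parametrize("offset", [-0.05, 0.02, 0.05])
    def test_planted_offset_recovered(self, acq_small, offset):
        spec = synth_spectrum(self.lactate_lines(offset), acq_small,
                              noise_sd=0.5, seed=9)
        out = calibrate_shift(spec, 1.32, 0.1)
        win = out.window(1.32 - 0.004, 1.32 + 0.004)
        apex = out.ppm[np.flatnonzero(win)[np.argmax(out.intensity[win])]]
        assert abs(apex - 1.32) <= out.ppm_spacing
        assert out.calibrated

    def test_already_calibrated_is_fixed_point(self, acq_small):
        spec = synth_spectrum(self.lactate_lines(0.0), acq_small)
        out = calibrate_shift(spec, 1.32, 0.1)
        applied = float(out.processing_log[-1].split("applied_shift=")[1].split(" ")[0])
        assert abs(applied) <= out.ppm_spacing

    def test_upfield_component_is_chosen(self, acq_small):
        # down-field doublet partner taller: calibration must still anchor
        # the up-field (lower ppm) line
        j_ppm = 7.0 / 600.0
        lines = [(1.32 + 0.03, 1.0, 4.0), (1.32 + j_ppm + 0.03, 1.3, 4.0)]
        spec = synth_spectrum(lines, acq_small)
        out = calibrate_shift(spec, 1.32, 0.1)
        win = out.window(1.315, 1.325)
        assert out.intensity[win].max() > 0.5 * out.intensity.max()

    def test_no_peak_raises(self, acq_small):
        spec = synth_spectrum([(3.0, 1.0, 4.0)], acq_small, noise_sd=0.01, seed=1)
        with pytest.raises(CalibrationError):
            calibrate_shift(spec, 1.32, 0.05)


class TestFullChain:
    def test_processing_log_order(self):
        cfg = SimConfig(n_ad=1, n_non_ad=0, seed=0,
                        acquisition=AcquisitionParams(n_points_td=4096))
        cohort = simulate_cohort(cfg)
        spec = preprocess(cohort.fids[cohort.individual_ids[0]])
        steps = [s.split("(")[0] for s in spec.processing_log]
        assert steps == ["apodize", "scale_first_point", "zero_fill",
                         "fourier_transform", "phase_correct",
                         "baseline_correct", "calibrate_shift"]
        assert spec.calibrated

    def test_deterministic(self):
        cfg = SimConfig(n_ad=1, n_non_ad=0, seed=5,
                        acquisition=AcquisitionParams(n_points_td=4096))
        cohort = simulate_cohort(cfg)
        fid = cohort.fids[cohort.individual_ids[0]]
        a = preprocess(fid)
        b = preprocess(fid)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        np.testing.assert_array_equal(a.ppm, b.ppm)
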