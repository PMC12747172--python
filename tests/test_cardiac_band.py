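import math

import numpy as np
import pytest

from nirsqc.cardiac_band import (
    CardiacBand,
    NoUsableChannelError,
    PsdEstimate,
    SpectralPeak,
    channel_cardiac_peak,
    detect_peaks,
    fit_gaussian_peak,
    fit_subject_band,
    flatten_spectrum,
    select_best_channels,
    smooth_psd,
    subject_cardiac_band,
    welch_psd,
)
from nirsqc.quality_indices import ChannelQualityMetrics
from nirsqc.synthetic import SimConfig, simulate_recording

FS = 8.0


def make_psd(power_db, fmax=4.0):
    freqs = np.linspace(0.01, fmax, len(power_db))
    return PsdEstimate(freqs=freqs, power_db=np.asarray(power_db, dtype=float))


def gaussian_bump(freqs, amp, cf, sigma):
    return amp * np.exp(-((freqs - cf) ** 2) / (2 * sigma**2))


class TestWelch:
    def test_sine_peak_location(self):
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 1.2 * t)
        psd = welch_psd(x, FS)
        peak_freq = psd.freqs[np.argmax(psd.power_db)]
        bin_width = psd.freqs[1] - psd.freqs[0]
        assert abs(peak_freq - 1.2) <= bin_width

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100_000)
        psd = welch_psd(x, 10.0, window_s=60.0)
        assert np.std(psd.power_db) < 1.5

    def test_zero_signal_floored(self):
        psd = welch_psd(np.zeros(2000), FS)
        assert np.all(psd.power_db == -120.0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            welch_psd(np.ones(4), FS)


class TestSmooth:
    def test_cubic_reproduced_exactly(self):
        n = 100
        idx = np.arange(n, dtype=float)
        power = 1e-3 * idx**3 - 0.05 * idx**2 + idx - 4.0
        psd = make_psd(power)
        out = smooth_psd(psd, 11)
        np.testing.assert_allclose(out.power_db, power, atol=1e-9)

    def test_impulse_bounded(self):
        power = np.zeros(64)
        power[32] = 10.0
        out = smooth_psd(make_psd(power), 11)
        assert np.max(np.abs(out.power_db)) <= 10.0 + 1e-9

    def test_noisy_bump_peak_preserved(self):
        rng = np.random.default_rng(5)
        freqs = np.linspace(0.01, 4.0, 240)
        power = gaussian_bump(freqs, 6.0, 1.2, 0.15) + 0.3 * rng.standard_normal(240)
        psd = PsdEstimate(freqs=freqs, power_db=power)
        out = smooth_psd(psd, 11)
        assert abs(np.argmax(out.power_db) - np.argmax(gaussian_bump(freqs, 6, 1.2, 0.15))) <= 1

    def test_frame_validation(self):
        psd = make_psd(np.zeros(50))
        with pytest.raises(ValueError):
            smooth_psd(psd, 10)
        with pytest.raises(ValueError):
            smooth_psd(psd, 51)


class TestFlatten:
    def test_quadratic_within_model_class(self):
        freqs = np.linspace(0.01, 4.0, 120)
        power = 2.0 + 0.5 * freqs - 0.1 * freqs**2
        flat = flatten_spectrum(PsdEstimate(freqs=freqs, power_db=power))
        np.testing.assert_allclose(flat.power_db, 0.0, atol=1e-9)

    def test_cubic_plus_bump_recovered(self):
        freqs = np.linspace(0.01, 4.0, 400)
        aperiodic = 1.0 - 2.0 * freqs + 0.3 * freqs**2 - 0.02 * freqs**3
        power = aperiodic + gaussian_bump(freqs, 6.0, 1.2, 0.15)
        flat = flatten_spectrum(PsdEstimate(freqs=freqs, power_db=power))
        peak_freq = freqs[np.argmax(flat.power_db)]
        assert abs(peak_freq - 1.2) < 0.1
        assert abs(np.max(flat.power_db) - 6.0) < 1.0

    def test_one_over_f_noise_flattens(self):
        from nirsqc.synthetic import _one_over_f_noise

        rng = np.random.default_rng(1)
        x = _one_over_f_noise(rng, 200_000, FS, 1.0)
        psd = welch_psd(x, FS, window_s=60.0)
        flat = flatten_spectrum(psd)
        mask = (flat.freqs >= 0.01) & (flat.freqs <= 4.0)
        assert np.mean(np.abs(flat.power_db[mask])) < 1.0

    def test_idempotent_refit(self):
        # exact within the model class (robust masking is a no-op there)
        freqs = np.linspace(0.01, 4.0, 200)
        power = 3.0 - freqs + 0.1 * freqs**3
        flat = flatten_spectrum(PsdEstimate(freqs=freqs, power_db=power))
        coeffs = np.polyfit(freqs, flat.power_db, 3)
        assert np.all(np.abs(coeffs) < 1e-6)
        again = flatten_spectrum(flat)
        np.testing.assert_allclose(again.power_db, flat.power_db, atol=1e-9)

    def test_too_few_bins(self):
        psd = make_psd(np.zeros(20))
        with pytest.raises(ValueError, match="8 bins"):
            flatten_spectrum(psd, fit_range=(0.01, 0.02))


class TestDetectPeaks:
    def test_flat_zero_spectrum(self):
        assert detect_peaks(make_psd(np.zeros(100))) == []

    def test_single_bump(self):
        freqs = np.linspace(0.01, 4.0, 200)
        power = gaussian_bump(freqs, 6.0, 1.2, 0.15)
        peaks = detect_peaks(PsdEstimate(freqs=freqs, power_db=power))
        assert len(peaks) == 1
        assert freqs[peaks[0]] == pytest.approx(1.2, abs=0.05)

    def test_prominence_gate(self):
        freqs = np.linspace(0.01, 4.0, 400)
        power = gaussian_bump(freqs, 6.0, 1.0, 0.1) + gaussian_bump(freqs, 0.3, 2.5, 0.1)
        peaks = detect_peaks(PsdEstimate(freqs=freqs, power_db=power))
        assert len(peaks) == 1


class TestGaussianFit:
    def setup_method(self):
        self.freqs = np.linspace(0.01, 4.0, 800)
        self.sigma = 0.15
        self.power = gaussian_bump(self.freqs, 6.0, 1.2, self.sigma)
        self.psd = PsdEstimate(freqs=self.freqs, power_db=self.power)

    def test_closed_form_widths(self):
        (idx,) = detect_peaks(self.psd)
        peak = fit_gaussian_peak(self.psd, idx)
        assert peak.fwhm == pytest.approx(2 * self.sigma * math.sqrt(2 * math.log(2)), abs=1e-3)
        assert peak.fw10m == pytest.approx(2 * self.sigma * math.sqrt(2 * math.log(10)), abs=1e-3)
        assert peak.fwhm == pytest.approx(0.3532, abs=1e-3)
        assert peak.fw10m == pytest.approx(0.6438, abs=1e-3)

    def test_width_ratio_sqrt_log_ratio(self):
        (idx,) = detect_peaks(self.psd)
        peak = fit_gaussian_peak(self.psd, idx)
        assert peak.fw10m / peak.fwhm == pytest.approx(
            math.sqrt(math.log(10) / math.log(2)), abs=1e-3
        )
        assert peak.fw10m / peak.fwhm == pytest.approx(1.8226, abs=1e-3)

    def test_perturbed_cf_recovery(self):
        rng = np.random.default_rng(8)
        power = self.power + 0.2 * rng.standard_normal(self.freqs.size)
        psd = PsdEstimate(freqs=self.freqs, power_db=power)
        idx = detect_peaks(psd)
        best = max(idx, key=lambda i: psd.power_db[i])
        peak = fit_gaussian_peak(psd, best)
        assert abs(peak.cf - 1.2) < 0.02


class TestSelectBestChannels:
    @staticmethod
    def metrics(cqi, sci, psp):
        return ChannelQualityMetrics(cv_percent=5.0, sci=sci, psp=psp, cqi=cqi)

    def test_strict_gate(self):
        channels, thr = select_best_channels(
            [self.metrics(0.95, 0.9, 0.2), self.metrics(0.5, 0.9, 0.2)]
        )
        assert channels == [0]
        assert thr == 0.9

    def test_relaxation_schedule(self):
        ms = [self.metrics(0.6, 0.85, 0.15)] * 3
        channels, thr = select_best_channels(ms)
        assert channels == [0, 1, 2]
        assert thr == pytest.approx(0.55)

    def test_floor_failure(self):
        ms = [self.metrics(0.95, 0.1, 0.2)] * 2
        with pytest.raises(NoUsableChannelError):
            select_best_channels(ms)


class TestSubjectBand:
    def test_single_peak(self):
        peak = SpectralPeak(cf=1.2, amplitude=6.0, fwhm=0.2, fw10m=0.4, prominence=6.0)
        band = subject_cardiac_band([peak])
        assert band.low == pytest.approx(1.0)
        assert band.high == pytest.approx(1.4)

    def test_medians(self):
        peaks = [
            SpectralPeak(cf=c, amplitude=6, fwhm=f * 0.5, fw10m=f, prominence=6)
            for c, f in [(1.1, 0.4), (1.2, 0.4), (1.3, 0.8)]
        ]
        band = subject_cardiac_band(peaks)
        assert band.cf_median == pytest.approx(1.2)
        assert (band.low, band.high) == (pytest.approx(1.0), pytest.approx(1.4))

    def test_outlier_robust(self):
        peaks = [
            SpectralPeak(cf=c, amplitude=6, fwhm=0.2, fw10m=0.4, prominence=6)
            for c in [1.2, 1.2, 3.0]
        ]
        assert subject_cardiac_band(peaks).cf_median == pytest.approx(1.2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            subject_cardiac_band([])


class TestFitSubjectBand:
    def test_recovers_hr(self, good_subject):
        rec, truth, _ = good_subject
        hr = truth.heart_rates[rec.subject_id]
        band = fit_subject_band(rec)
        assert band.low < hr < band.high
        assert abs(band.cf_median - hr) <= 0.05

    def test_infant_range_not_clipped(self):
        cfg = SimConfig(
            n_subjects=1, n_channels=8, duration_s=300, fs=FS,
            hr_range_hz=(2.4, 2.4), seed=1,
        )
        rec, _ = simulate_recording(cfg, 0)
        band = fit_subject_band(rec)
        assert abs(band.cf_median - 2.4) <= 0.05

    def test_all_coupling_loss_errors(self):
        cfg = SimConfig(
            n_subjects=1, n_channels=4, duration_s=120, fs=FS, seed=2,
            low_fraction=1.0,
            mode_weights={"coupling_loss": 1.0, "motion_burst": 0.0, "saturation": 0.0},
        )
        rec, _ = simulate_recording(cfg, 0)
        with pytest.raises(NoUsableChannelError):
            fit_subject_band(rec)

    def test_median_outlier_invariance(self, good_subject):
        """Adding a noisy channel must not move the median CF when several
        good channels already contribute."""
        rec, truth, _ = good_subject
        band = fit_subject_band(rec)
        peak = channel_cardiac_peak(
            np.sin(2 * np.pi * 3.0 * np.arange(2400) / FS)
            + 0.01 * np.random.default_rng(0).standard_normal(2400),
            FS,
        )
        from nirsqc.cardiac_band import subject_cardiac_band as scb

        peaks = [
            SpectralPeak(
                cf=band.cf_median, amplitude=6,
                fwhm=band.fw10m_median / 2, fw10m=band.fw10m_median, prominence=6,
            )
        ] * 3 + [peak]
        assert scb(peaks).cf_median == pytest.approx(band.cf_median)
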