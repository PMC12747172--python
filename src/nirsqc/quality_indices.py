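"""Index-based channel quality metrics: CV, SCI, PSP and the composite CQI.

The scalp coupling index (SCI) and the cardiac peak spectral power (PSP)
follow the usual coupling-index semantics: both wavelength series are
band-pass filtered in a fixed cardiac band (0.5-2.5 Hz), z-normalized,
and compared - SCI as the zero-lag Pearson correlation, PSP as the
concentration of the cross-correlation power spectrum inside the band.
The composite quality index (CQI) is the fraction of non-overlapping
windows in which both SCI and PSP pass their thresholds.

Degenerate inputs (zero variance after filtering, e.g. a saturated
channel) yield SCI = PSP = 0 with a warning: "no cardiac evidence" is
exactly the verdict wanted for such channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

FIXED_CARDIAC_BAND = (0.5, 2.5)

CV_THRESHOLD_DEFAULT = 15.0
SCI_THRESHOLD_DEFAULT = 0.75
PSP_THRESHOLD_DEFAULT = 0.1
CQI_WINDOW_S_DEFAULT = 5.0

#: half-width in bins of the spectral neighborhood pooled around the
#: cross-correlation spectrum peak when computing PSP
_PSP_PEAK_HALFWIDTH_BINS = 2


@dataclass
class ChannelQualityMetrics:
    cv_percent: float
    sci: float
    psp: float
    cqi: float


def coefficient_of_variation(intensity_column: np.ndarray) -> float:
    """CV in percent: 100 * sample standard deviation / mean.

    Uses the unbiased (n-1) standard deviation.
    """
    x = np.asarray(intensity_column, dtype=float)
    if x.size < 2:
        raise ValueError("series must have at least 2 samples")
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero-mean series has undefined CV")
    return float(100.0 * x.std(ddof=1) / mean)


def cv_is_low_quality(cv_percent: float, threshold: float = CV_THRESHOLD_DEFAULT) -> bool:
    return cv_percent > threshold


def _cardiac_bandpass(x: np.ndarray, fs: float, band=FIXED_CARDIAC_BAND) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, truncated at Nyquist."""
    low, high = band
    nyq = fs / 2.0
    if high >= nyq:
        warnings.warn(
            f"band upper edge {high} Hz truncated below Nyquist {nyq} Hz",
            stacklevel=3,
        )
        high = 0.95 * nyq
    if low >= high:
        raise ValueError(f"degenerate band [{low}, {high}] at fs={fs}")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    padlen = min(len(x) - 1, 3 * 8)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def _znorm(x: np.ndarray, raw: np.ndarray):
    """Z-normalize the filtered series; None when degenerate.

    Degeneracy is judged against the raw series too: a constant segment
    filters to pure numerical residue that would otherwise correlate
    perfectly between identical wavelength columns.
    """
    sd = x.std()
    raw_scale = float(np.ptp(raw))
    if sd == 0 or not np.isfinite(sd) or raw_scale == 0 or sd < 1e-9 * raw_scale:
        return None
    return (x - x.mean()) / sd


def sci(w1: np.ndarray, w2: np.ndarray, fs: float, band=FIXED_CARDIAC_BAND) -> float:
    """Scalp coupling index: zero-lag correlation of the band-filtered,
    z-normalized wavelength series. Zero-variance inputs return 0."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape:
        raise ValueError("wavelength series must have equal length")
    f1 = _znorm(_cardiac_bandpass(w1, fs, band), w1)
    f2 = _znorm(_cardiac_bandpass(w2, fs, band), w2)
    if f1 is None or f2 is None:
        warnings.warn("zero variance after cardiac-band filtering; SCI = 0")
        return 0.0
    return float(np.dot(f1, f2) / len(f1))


def sci_is_low_quality(value: float, threshold: float = SCI_THRESHOLD_DEFAULT) -> bool:
    return value < threshold


def psp(
    w1: np.ndarray,
    w2: np.ndarray,
    fs: float,
    band=FIXED_CARDIAC_BAND,
) -> float:
    """Cardiac peak spectral power of the wavelength cross-correlation.

    The band-filtered, z-normalized series are cross-correlated (biased
    estimator); the power spectrum of the windowed cross-correlation is
    normalized to unit total power, and the value returned is the power
    pooled in a small neighborhood of the spectral peak inside the band.
    A shared periodic cardiac component concentrates the spectrum (PSP
    near 1); independent noise spreads it (PSP near 0).
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape:
        raise ValueError("wavelength series must have equal length")
    f1 = _znorm(_cardiac_bandpass(w1, fs, band), w1)
    f2 = _znorm(_cardiac_bandpass(w2, fs, band), w2)
    if f1 is None or f2 is None:
        warnings.warn("zero variance after cardiac-band filtering; PSP = 0")
        return 0.0
    n = len(f1)
    xcorr = signal.correlate(f1, f2, mode="full") / n
    win = np.hamming(len(xcorr))
    spec = np.abs(np.fft.rfft(xcorr * win)) ** 2
    total = spec.sum()
    if total == 0:
        return 0.0
    freqs = np.fft.rfftfreq(len(xcorr), d=1.0 / fs)
    low, high = band
    in_band = (freqs >= low) & (freqs <= min(high, fs / 2))
    if not np.any(in_band):
        return 0.0
    band_idx = np.flatnonzero(in_band)
    peak = band_idx[np.argmax(spec[band_idx])]
    lo = max(0, peak - _PSP_PEAK_HALFWIDTH_BINS)
    hi = min(len(spec), peak + _PSP_PEAK_HALFWIDTH_BINS + 1)
    return float(spec[lo:hi].sum() / total)


def cqi(
    w1: np.ndarray,
    w2: np.ndarray,
    fs: float,
    window_s: float = CQI_WINDOW_S_DEFAULT,
    sci_thr: float = SCI_THRESHOLD_DEFAULT,
    psp_thr: float = PSP_THRESHOLD_DEFAULT,
    band=FIXED_CARDIAC_BAND,
) -> float:
    """Composite quality index: fraction of non-overlapping windows in
    which both the SCI and the PSP pass their thresholds."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    win = int(round(window_s * fs))
    n_win = len(w1) // win if win > 0 else 0
    if n_win < 2:
        raise ValueError(
            f"record of {len(w1)} samples too short for >=2 windows of {window_s} s"
        )
    passed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate windows legitimately score 0
        for k in range(n_win):
            a, b = k * win, (k + 1) * win
            s_val = sci(w1[a:b], w2[a:b], fs, band)
            p_val = psp(w1[a:b], w2[a:b], fs, band)
            if s_val >= sci_thr and p_val >= psp_thr:
                passed += 1
    return passed / n_win


def channel_metrics(
    intensity: np.ndarray,
    fs: float,
    window_s: float = CQI_WINDOW_S_DEFAULT,
    sci_thr: float = SCI_THRESHOLD_DEFAULT,
    psp_thr: float = PSP_THRESHOLD_DEFAULT,
) -> ChannelQualityMetrics:
    """All four metrics for one channel's (time, 2) intensity block.

    CV is the worse (larger) of the two wavelengths' values; SCI/PSP/CQI
    are computed between the two wavelength series.
    """
    w1, w2 = intensity[:, 0], intensity[:, 1]
    cv_val = max(coefficient_of_variation(w1), coefficient_of_variation(w2))
    return ChannelQualityMetrics(
        cv_percent=cv_val,
        sci=sci(w1, w2, fs),
        psp=psp(w1, w2, fs),
        cqi=cqi(w1, w2, fs, window_s=window_s, sci_thr=sci_thr, psp_thr=psp_thr),
    )
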