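"""Subject-specific cardiac frequency band from oxyhemoglobin spectra.

Pipeline per subject: preselect the best channels with the composite
quality gates, estimate each channel's Welch power spectrum in dB,
smooth it (Savitzky-Golay, order 3), remove the aperiodic 1/f-like
background with a cubic fit in dB, detect prominent peaks, fit a
Gaussian to the cardiac candidate, and define the band as

    [median(CF) - median(FW10M)/2,  median(CF) + median(FW10M)/2]

with medians over the contributing channels.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal

from nirsqc.hemodynamics import recording_to_hb
from nirsqc.quality_indices import ChannelQualityMetrics, channel_metrics
from nirsqc.signal_io import Recording

logger = logging.getLogger(__name__)

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))
FW10M_FACTOR = 2.0 * math.sqrt(2.0 * math.log(10.0))

DB_FLOOR = -120.0

WELCH_WINDOW_S_DEFAULT = 60.0
SG_FRAME_BINS_DEFAULT = 11
MIN_PROMINENCE_DB_DEFAULT = 0.5
CQI_RELAX_STEP = 0.05
HR_SEARCH_RANGE_HZ = (0.5, 3.5)

PRESELECT_CQI_THR = 0.9
PRESELECT_SCI_THR = 0.8
PRESELECT_PSP_THR = 0.1


class NoUsableChannelError(RuntimeError):
    """No channel passes the quality gates even at the relaxed floor."""


@dataclass
class PsdEstimate:
    """Welch power spectrum in dB with smoothing metadata."""

    freqs: np.ndarray
    power_db: np.ndarray
    window_s: float | None = None
    sg_frame_bins: int | None = None
    sg_order: int | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power_db = np.asarray(self.power_db, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.power_db.shape:
            raise ValueError("freqs and power_db must be 1-D and equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.all(np.isfinite(self.power_db)):
            raise ValueError("power_db must be finite")


@dataclass
class SpectralPeak:
    """Gaussian-fitted spectral peak of one channel."""

    cf: float
    amplitude: float
    fwhm: float
    fw10m: float
    prominence: float
    fit_converged: bool = True

    def __post_init__(self) -> None:
        if not (self.fw10m > self.fwhm > 0):
            raise ValueError("requires fw10m > fwhm > 0")


@dataclass
class CardiacBand:
    """Subject-level cardiac band: median CF +/- median FW10M / 2."""

    cf_median: float
    fw10m_median: float
    contributing_channels: list[int] = field(default_factory=list)

    @property
    def low(self) -> float:
        return self.cf_median - self.fw10m_median / 2.0

    @property
    def high(self) -> float:
        return self.cf_median + self.fw10m_median / 2.0

    def to_dict(self) -> dict:
        return {
            "cf_median_hz": self.cf_median,
            "fw10m_median_hz": self.fw10m_median,
            "low_hz": self.low,
            "high_hz": self.high,
            "contributing_channels": list(self.contributing_channels),
        }


def welch_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = WELCH_WINDOW_S_DEFAULT,
    overlap: float = 0.5,
) -> PsdEstimate:
    """Welch periodogram with a Hamming window and 50% overlap, in dB.

    Zero power bins are floored at -120 dB rather than -inf.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    nperseg = min(nperseg, len(x))
    if nperseg < 8:
        raise ValueError(f"series of {len(x)} samples too short for Welch PSD")
    freqs, pxx = signal.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
    )
    # drop DC: downstream fitting works on log-frequency-free dB values
    freqs, pxx = freqs[1:], pxx[1:]
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(pxx)
    power_db = np.maximum(power_db, DB_FLOOR)
    return PsdEstimate(freqs=freqs, power_db=power_db, window_s=window_s)


def smooth_psd(psd: PsdEstimate, frame_bins: int = SG_FRAME_BINS_DEFAULT) -> PsdEstimate:
    """Savitzky-Golay smoothing (order 3) of the dB spectrum."""
    if frame_bins % 2 == 0 or frame_bins <= 3:
        raise ValueError("frame_bins must be odd and > 3")
    if frame_bins > psd.power_db.size:
        raise ValueError(
            f"frame of {frame_bins} bins exceeds spectrum of {psd.power_db.size} bins"
        )
    smoothed = signal.savgol_filter(psd.power_db, frame_bins, polyorder=3)
    return replace(psd, power_db=smoothed, sg_frame_bins=frame_bins, sg_order=3)


def flatten_spectrum(
    psd: PsdEstimate, fit_range: tuple[float, float] | None = None
) -> PsdEstimate:
    """Remove the aperiodic background: fit a cubic (in frequency) to the
    dB spectrum over ``fit_range`` and subtract it everywhere.

    The fit is made robust to periodic peaks with a second pass that
    excludes the bins with the largest positive residuals of the first
    fit, so a strong cardiac peak does not drag the background upward.
    """
    if fit_range is None:
        fit_range = (0.01, psd.freqs[-1])
    mask = (psd.freqs >= fit_range[0]) & (psd.freqs <= fit_range[1])
    if mask.sum() < 8:
        raise ValueError("need at least 8 bins inside the aperiodic fit range")
    f = psd.freqs[mask]
    p = psd.power_db[mask]
    # centered/scaled design for conditioning
    first = np.polynomial.polynomial.Polynomial.fit(f, p, deg=3)
    resid = p - first(f)
    keep = resid <= np.percentile(resid, 66.7)
    if keep.sum() >= 8:
        coeffs = np.polynomial.polynomial.Polynomial.fit(f[keep], p[keep], deg=3)
    else:
        coeffs = first
    residual = psd.power_db - coeffs(psd.freqs)
    return replace(psd, power_db=residual)


def detect_peaks(
    flat: PsdEstimate, min_prominence_db: float = MIN_PROMINENCE_DB_DEFAULT
) -> list[int]:
    """Indices of local maxima with topographic prominence above the gate,
    searched over the entire frequency range."""
    idx, _props = signal.find_peaks(flat.power_db, prominence=min_prominence_db)
    return [int(i) for i in idx]


def _gaussian(f, a, cf, sigma, offset):
    return a * np.exp(-((f - cf) ** 2) / (2.0 * sigma**2)) + offset


def fit_gaussian_peak(
    flat: PsdEstimate, peak_index: int, window_halfwidth_factor: float = 3.0
) -> SpectralPeak:
    """Nonlinear least-squares Gaussian fit around a detected peak.

    The fit window is +/- ``window_halfwidth_factor`` times the empirical
    half-prominence width around the apex. A non-convergent fit falls
    back to empirical widths and is flagged.
    """
    freqs, power = flat.freqs, flat.power_db
    apex_amp = power[peak_index]
    prominences, left_bases, right_bases = signal.peak_prominences(power, [peak_index])
    prominence = float(prominences[0])
    half = apex_amp - prominence / 2.0
    left = peak_index
    while left > left_bases[0] and power[left] > half:
        left -= 1
    right = peak_index
    while right < right_bases[0] and power[right] > half:
        right += 1
    half_width_hz = max(
        (freqs[right] - freqs[left]) / 2.0, freqs[1] - freqs[0]
    )
    lo = freqs[peak_index] - window_halfwidth_factor * half_width_hz
    hi = freqs[peak_index] + window_halfwidth_factor * half_width_hz
    mask = (freqs >= lo) & (freqs <= hi)
    f_win = freqs[mask]
    p_win = power[mask]
    baseline = p_win.min()
    sigma0 = half_width_hz / math.sqrt(2.0 * math.log(2.0))
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            _gaussian,
            f_win,
            p_win,
            p0=[apex_amp - baseline, freqs[peak_index], sigma0, baseline],
            bounds=(
                [0.0, f_win[0], 1e-4, -np.inf],
                [np.inf, f_win[-1], freqs[-1], np.inf],
            ),
            maxfev=5000,
        )
        amp, cf, sigma, _offset = popt
    except (RuntimeError, ValueError):
        warnings.warn("Gaussian peak fit did not converge; using empirical widths")
        converged = False
        amp = apex_amp
        cf = float(freqs[peak_index])
        sigma = sigma0
    return SpectralPeak(
        cf=float(cf),
        amplitude=float(amp),
        fwhm=float(FWHM_FACTOR * sigma),
        fw10m=float(FW10M_FACTOR * sigma),
        prominence=prominence,
        fit_converged=converged,
    )


def select_best_channels(
    metrics: list[ChannelQualityMetrics],
    cqi_thr: float = PRESELECT_CQI_THR,
    sci_thr: float = PRESELECT_SCI_THR,
    psp_thr: float = PRESELECT_PSP_THR,
    relax_step: float = CQI_RELAX_STEP,
) -> tuple[list[int], float]:
    """Channels passing cqi > cqi_thr AND sci > sci_thr AND psp > psp_thr.

    If the set is empty the CQI threshold is relaxed in ``relax_step``
    decrements (floor 0), holding the SCI/PSP gates fixed, until at least
    one channel passes. Returns (channel subset, final cqi threshold).
    """
    if not metrics:
        raise ValueError("at least one channel is required")
    thr = cqi_thr
    while True:
        selected = [
            i
            for i, m in enumerate(metrics)
            if m.cqi > thr and m.sci > sci_thr and m.psp > psp_thr
        ]
        if selected:
            return selected, thr
        if thr <= 0:
            raise NoUsableChannelError("no usable channel after relaxing CQI to 0")
        # round to kill float drift so the schedule hits 0.85, 0.80, ...
        new_thr = max(0.0, round(thr - relax_step, 10))
        logger.info("no channel at cqi>%0.2f; relaxing to %0.2f", thr, new_thr)
        thr = new_thr


def subject_cardiac_band(peaks: list[SpectralPeak], channels: list[int] | None = None) -> CardiacBand:
    """Median CF +/- median FW10M / 2 over the contributing channels."""
    if not peaks:
        raise ValueError("at least one spectral peak is required")
    cf_median = float(np.median([p.cf for p in peaks]))
    fw10m_median = float(np.median([p.fw10m for p in peaks]))
    return CardiacBand(
        cf_median=cf_median,
        fw10m_median=fw10m_median,
        contributing_channels=list(channels) if channels is not None else [],
    )


def channel_cardiac_peak(
    hbo: np.ndarray,
    fs: float,
    window_s: float = WELCH_WINDOW_S_DEFAULT,
    sg_frame_bins: int = SG_FRAME_BINS_DEFAULT,
    min_prominence_db: float = MIN_PROMINENCE_DB_DEFAULT,
    hr_range: tuple[float, float] = HR_SEARCH_RANGE_HZ,
) -> SpectralPeak | None:
    """Full single-channel chain: PSD -> smooth -> flatten -> peaks ->
    Gaussian fit of the cardiac candidate.

    Among retained peaks the cardiac candidate is the most prominent one
    whose frequency lies in the plausibility range (tie-break: higher
    prominence, then lower frequency). Returns None when no peak
    qualifies.
    """
    psd = welch_psd(hbo, fs, window_s=window_s)
    frame = min(sg_frame_bins, psd.power_db.size if psd.power_db.size % 2 else psd.power_db.size - 1)
    smoothed = smooth_psd(psd, frame_bins=frame) if frame > 3 else psd
    flat = flatten_spectrum(smoothed)
    peak_idx = detect_peaks(flat, min_prominence_db=min_prominence_db)
    candidates = []
    for i in peak_idx:
        f = flat.freqs[i]
        if hr_range[0] <= f <= hr_range[1]:
            prom = signal.peak_prominences(flat.power_db, [i])[0][0]
            candidates.append((-prom, f, i))
    if not candidates:
        return None
    candidates.sort()
    best = candidates[0][2]
    return fit_gaussian_peak(flat, best)


def fit_subject_band(
    rec: Recording,
    window_s: float = WELCH_WINDOW_S_DEFAULT,
    sg_frame_bins: int = SG_FRAME_BINS_DEFAULT,
    min_prominence_db: float = MIN_PROMINENCE_DB_DEFAULT,
    hr_range: tuple[float, float] = HR_SEARCH_RANGE_HZ,
    dpf: float | str | None = None,
) -> CardiacBand:
    """Subject-level band from a raw recording.

    Channels are preselected on the raw optical series with the composite
    quality gates; the spectral chain then runs on the oxyhemoglobin
    series of the selected channels only.
    """
    metrics = [
        channel_metrics(rec.intensity[:, ch, :], rec.fs)
        for ch in range(rec.n_channels)
    ]
    selected, final_thr = select_best_channels(metrics)
    if final_thr < PRESELECT_CQI_THR:
        logger.info(
            "subject %s: CQI threshold relaxed to %.2f", rec.subject_id, final_thr
        )
    hb = recording_to_hb(rec, dpf=dpf)
    peaks = []
    contributing = []
    for ch in selected:
        peak = channel_cardiac_peak(
            hb.hbo[:, ch],
            rec.fs,
            window_s=window_s,
            sg_frame_bins=sg_frame_bins,
            min_prominence_db=min_prominence_db,
            hr_range=hr_range,
        )
        if peak is not None:
            peaks.append(peak)
            contributing.append(ch)
    if not peaks:
        raise NoUsableChannelError(
            f"subject {rec.subject_id}: no cardiac peak found on any preselected channel"
        )
    return subject_cardiac_band(peaks, contributing)
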