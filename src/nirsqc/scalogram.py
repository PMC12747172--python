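"""Morlet scalograms and their standardization into 224x224 RGB images.

Each segment is band-pass filtered in the subject's cardiac band, its
Morlet CWT magnitude is computed on a log-spaced frequency grid, all
segment scalograms of one channel are jointly min-max normalized, the
frequency axis is shifted so the subject's cardiac center frequency
lands on a fixed reference row (row 30, 1-based from the top), the time
axis is bilinearly rescaled to a uniform width, and the scalar field is
finally rendered through the jet colormap.

Conventions: the highest frequency is the top image row; the RGB
conversion happens after all geometric operations, so interpolation
never mixes colormap channels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from nirsqc.cardiac_band import CardiacBand
from nirsqc.imageops import bilinear_resize, crop_or_pad_rows, shift_rows
from nirsqc.signal_io import SegmentRef

MORLET_W0 = 6.0
VOICES_PER_OCTAVE = 12
GRID_FMIN_HZ = 0.2
GRID_FMAX_HZ = 5.0
IMAGE_SIZE = 224
CARDIAC_ROW = 30  # 1-based from the top


@dataclass
class Scalogram:
    """CWT magnitude, rows ordered from the highest frequency down."""

    magnitude: np.ndarray  # (freq, time), nonnegative
    freqs: np.ndarray  # Hz, strictly decreasing
    times: np.ndarray  # s

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.magnitude.shape != (self.freqs.size, self.times.size):
            raise ValueError("magnitude shape inconsistent with freqs/times")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be nonnegative")
        if self.freqs.size > 1 and np.any(np.diff(self.freqs) >= 0):
            raise ValueError("freqs must be strictly decreasing (top row first)")


@dataclass
class StandardizedImage:
    """224x224x3 jet-rendered image with the cardiac band at row 30."""

    pixels: np.ndarray
    cardiac_row: int
    provenance: SegmentRef | None = None
    field: np.ndarray | None = None  # pre-colormap scalar field, kept for analysis

    def __post_init__(self) -> None:
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(f"pixels must be {IMAGE_SIZE}x{IMAGE_SIZE}x3")


def default_freq_grid(fs: float) -> np.ndarray:
    """Log-spaced grid, 12 voices/octave, descending, capped below Nyquist."""
    fmax = min(GRID_FMAX_HZ, 0.95 * fs / 2.0)
    if fmax <= GRID_FMIN_HZ:
        raise ValueError(f"sampling rate {fs} Hz too low for the CWT grid")
    n_octaves = math.log2(fmax / GRID_FMIN_HZ)
    n = int(math.floor(n_octaves * VOICES_PER_OCTAVE)) + 1
    grid = GRID_FMIN_HZ * 2.0 ** (np.arange(n) / VOICES_PER_OCTAVE)
    return grid[::-1].copy()


def bandpass_cardiac(x: np.ndarray, fs: float, band: CardiacBand) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass on [band.low, band.high]."""
    if not (0 < band.low < band.high < fs / 2.0):
        raise ValueError(
            f"band [{band.low:.3f}, {band.high:.3f}] Hz outside (0, {fs / 2:.3f})"
        )
    sos = signal.butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def cwt_morlet(
    x: np.ndarray, fs: float, freq_grid: np.ndarray | None = None
) -> Scalogram:
    """Analytic Morlet (center frequency parameter 6) CWT magnitude.

    Computed in the frequency domain with L1-type normalization so that a
    unit-amplitude sine produces a comparable ridge magnitude at every
    grid frequency.
    """
    x = np.asarray(x, dtype=float)
    if freq_grid is None:
        freq_grid = default_freq_grid(fs)
    freq_grid = np.asarray(freq_grid, dtype=float)
    if np.any(freq_grid >= fs / 2.0) or np.any(freq_grid <= 0):
        raise ValueError("frequency grid outside (0, Nyquist)")
    fmin = freq_grid.min()
    if len(x) < 4 * fs / fmin:
        raise ValueError(
            f"need >= 4 cycles of {fmin} Hz: {len(x)} samples at {fs} Hz is too short"
        )
    n = len(x)
    xf = np.fft.fft(x - x.mean())
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)
    mag = np.empty((freq_grid.size, n))
    pos = omega > 0
    for i, f in enumerate(freq_grid):
        s = MORLET_W0 / (2.0 * np.pi * f)  # scale in seconds
        psi_hat = np.zeros(n)
        psi_hat[pos] = np.exp(-0.5 * (s * omega[pos] - MORLET_W0) ** 2)
        mag[i] = np.abs(np.fft.ifft(xf * psi_hat))
    times = np.arange(n) / fs
    return Scalogram(magnitude=mag, freqs=freq_grid, times=times)


def normalize_segments(scalograms: list[Scalogram]) -> list[Scalogram]:
    """Joint min-max normalization over all segments of one channel.

    The min and max are pooled across segments so segment contrast stays
    comparable; an all-constant pool maps to zeros with a warning.
    """
    if not scalograms:
        raise ValueError("at least one segment scalogram is required")
    lo = min(float(s.magnitude.min()) for s in scalograms)
    hi = max(float(s.magnitude.max()) for s in scalograms)
    if hi <= lo:
        warnings.warn("all segment scalograms are constant; normalized to 0")
        return [
            Scalogram(np.zeros_like(s.magnitude), s.freqs, s.times) for s in scalograms
        ]
    return [
        Scalogram((s.magnitude - lo) / (hi - lo), s.freqs, s.times) for s in scalograms
    ]


def jet_rgb(value: np.ndarray | float) -> np.ndarray:
    """MATLAB jet colormap, piecewise linear over [0, 1].

    Breakpoints: 0 -> (0, 0, 0.5), 0.125 -> (0, 0, 1), 0.375 -> (0, 1, 1),
    0.625 -> (1, 1, 0), 0.875 -> (1, 0, 0), 1 -> (0.5, 0, 0).
    """
    v = np.clip(np.asarray(value, dtype=float), 0.0, 1.0)
    r = np.clip(np.minimum(4.0 * v - 1.5, -4.0 * v + 4.5), 0.0, 1.0)
    g = np.clip(np.minimum(4.0 * v - 0.5, -4.0 * v + 3.5), 0.0, 1.0)
    b = np.clip(np.minimum(4.0 * v + 0.5, -4.0 * v + 2.5), 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


def standardize_field(
    norm: Scalogram,
    band: CardiacBand,
    target_row: int = CARDIAC_ROW,
    size: int = IMAGE_SIZE,
) -> np.ndarray:
    """Geometric standardization of a normalized scalogram (scalar field).

    The row nearest ``band.cf_median`` is shifted to ``target_row``
    (1-based from the top); vacated rows are zero-padded, overflow
    cropped; rows are then cropped/padded to ``size`` and the time axis
    bilinearly rescaled to ``size`` columns.
    """
    freqs = norm.freqs
    if not (freqs.min() <= band.cf_median <= freqs.max()):
        raise ValueError(
            f"cf_median {band.cf_median:.3f} Hz outside grid "
            f"[{freqs.min():.3f}, {freqs.max():.3f}]"
        )
    cf_idx = int(np.argmin(np.abs(freqs - band.cf_median)))
    offset = (target_row - 1) - cf_idx
    shifted = shift_rows(norm.magnitude, offset)
    framed = crop_or_pad_rows(shifted, size)
    return bilinear_resize(framed, (size, size))


def align_and_resize(
    norm: Scalogram,
    band: CardiacBand,
    provenance: SegmentRef | None = None,
    target_row: int = CARDIAC_ROW,
) -> StandardizedImage:
    """Standardize a normalized scalogram and render it through jet."""
    field = standardize_field(norm, band, target_row=target_row)
    return StandardizedImage(
        pixels=jet_rgb(field),
        cardiac_row=target_row,
        provenance=provenance,
        field=field,
    )


def segment_scalograms(
    series: np.ndarray,
    fs: float,
    band: CardiacBand,
    segments: list[SegmentRef],
    freq_grid: np.ndarray | None = None,
) -> list[StandardizedImage]:
    """Full per-channel chain: band filter, CWT per segment, joint
    normalization, then standardization of every segment."""
    filtered = bandpass_cardiac(series, fs, band)
    raw = [
        cwt_morlet(filtered[ref.start_sample : ref.end_sample], fs, freq_grid)
        for ref in segments
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normed = normalize_segments(raw)
    return [
        align_and_resize(s, band, provenance=ref)
        for s, ref in zip(normed, segments)
    ]
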