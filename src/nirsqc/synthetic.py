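"""Seeded simulator of dual-wavelength resting-state fNIRS recordings.

Each good channel carries an oxyhemoglobin time course built from a
cardiac oscillation at the subject's heart rate (with slow amplitude
modulation and a 20% second harmonic), a Mayer wave (~0.1 Hz), a
respiratory wave (~0.25 Hz) and 1/f drift; deoxyhemoglobin is the usual
anticorrelated copy. The forward Beer-Lambert model turns the
hemodynamics into two wavelength OD series that share the cardiac
signature, and intensity is I0 * exp(-OD) plus sensor noise.

Low-quality modes, applied per segment:

* ``coupling_loss`` - cardiac amplitude suppressed to ~0 and large
  uncorrelated per-wavelength noise added;
* ``motion_burst``  - spikes and baseline steps over an annotated span
  covering more than half the segment;
* ``saturation``    - intensity clipped to a constant value.

A segment's ground-truth label is low iff the cardiac component is
suppressed or masked over more than half (by default) of its duration,
mirroring the visual annotation rule the pipeline was built around.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from nirsqc import signal_io
from nirsqc.hemodynamics import MbllParams, forward_mbll
from nirsqc.signal_io import ChannelGeometry, Recording, SegmentRef, segment_channels

LOW_MODES = ("coupling_loss", "motion_burst", "saturation")


@dataclass
class SimConfig:
    n_subjects: int = 10
    n_channels: int = 8
    duration_s: float = 300.0
    fs: float = 8.0
    n_segments: int = 5
    hr_range_hz: tuple[float, float] = (0.83, 1.5)
    cardiac_amplitude_um: float = 0.8
    mayer_amplitude_um: float = 0.3
    mayer_freq_hz: float = 0.1
    resp_amplitude_um: float = 0.25
    resp_freq_hz: float = 0.25
    drift_exponent: float = 1.0
    drift_scale_um: float = 0.5
    noise_sd: float = 2e-4  # sensor noise, fraction of I0
    low_fraction: float = 0.0
    mode_weights: dict[str, float] = field(
        default_factory=lambda: {
            "coupling_loss": 0.5,
            "motion_burst": 0.3,
            "saturation": 0.2,
        }
    )
    low_rule_fraction: float = 0.5  # suppressed/masked > this fraction => low
    #: per-segment low probability on a bad-leaning channel; quality is
    #: clustered by channel (coupling trouble persists), with the
    #: good-leaning probability chosen so E[low] = low_fraction exactly
    channel_badness: float = 0.9
    hbr_ratio: float = -0.3
    i0: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        nyq = self.fs / 2.0
        for rate in (self.hr_range_hz[1], self.mayer_freq_hz, self.resp_freq_hz):
            if rate >= nyq:
                raise ValueError(f"rate {rate} Hz not below Nyquist {nyq} Hz")
        if not (0.0 <= self.low_fraction <= 1.0):
            raise ValueError("low_fraction must be in [0, 1]")
        w = self.mode_weights
        if set(w) - set(LOW_MODES):
            raise ValueError(f"unknown low-quality modes: {set(w) - set(LOW_MODES)}")
        total = sum(w.values())
        if total <= 0 or abs(total - 1.0) > 1e-9:
            raise ValueError("mode weights must sum to 1")
        if self.n_subjects < 1 or self.n_channels < 1 or self.n_segments < 1:
            raise ValueError("counts must be positive")
        if int(self.duration_s * self.fs) < self.n_segments:
            raise ValueError("recording too short for the requested segmentation")


@dataclass
class ArtifactSpan:
    kind: str
    start_sample: int
    end_sample: int


@dataclass
class GroundTruth:
    labels: dict[SegmentRef, str]
    heart_rates: dict[str, float]
    artifacts: dict[SegmentRef, list[ArtifactSpan]]
    #: injected oxyhemoglobin time courses (uM), per subject: (time, channel)
    hbo: dict[str, np.ndarray] = field(default_factory=dict)

    def label_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": ref.subject_id,
                "channel": ref.channel_index,
                "segment": ref.segment_index,
                "label": label,
            }
            for ref, label in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows, columns=signal_io.LABEL_COLUMNS)


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit std."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _segment_plan(
    cfg: SimConfig, rng: np.random.Generator, n_segments: int
) -> list[str | None]:
    """Per-segment quality plan for one channel: None = good, else mode.

    Quality clusters by channel: the channel is bad-leaning with
    probability ``low_fraction`` (per-segment low probability
    ``channel_badness``); the good-leaning per-segment probability is
    scaled so the expected overall low share equals ``low_fraction``.
    """
    f, c = cfg.low_fraction, cfg.channel_badness
    if f >= 1.0:
        p_low = 1.0
    elif f <= 0.0:
        p_low = 0.0
    elif rng.random() < f:
        p_low = c
    else:
        p_low = f * (1.0 - c) / (1.0 - f)
    plan: list[str | None] = []
    modes = list(cfg.mode_weights)
    weights = np.array([cfg.mode_weights[m] for m in modes])
    for _ in range(n_segments):
        if rng.random() < p_low:
            plan.append(str(rng.choice(modes, p=weights)))
        else:
            plan.append(None)
    return plan


def simulate_recording(
    cfg: SimConfig, subject_index: int
) -> tuple[Recording, GroundTruth]:
    """Simulate one subject's recording with per-segment ground truth."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, subject_index]))
    subject_id = f"sim{subject_index:03d}"
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    hr = float(rng.uniform(*cfg.hr_range_hz))
    montage = [ChannelGeometry(ch, ch, 30.0, False) for ch in range(cfg.n_channels)]
    params = MbllParams.for_recording(
        Recording(
            subject_id=subject_id,
            intensity=np.ones((2, cfg.n_channels, 2)),
            fs=cfg.fs,
            montage=montage,
        )
    )
    seg_len = n // cfg.n_segments

    intensity = np.empty((n, cfg.n_channels, 2))
    hbo_truth = np.empty((n, cfg.n_channels))
    labels: dict[SegmentRef, str] = {}
    artifacts: dict[SegmentRef, list[ArtifactSpan]] = {}

    for ch in range(cfg.n_channels):
        plan = _segment_plan(cfg, rng, cfg.n_segments)
        # cardiac amplitude envelope: slow modulation, zeroed where coupling
        # is lost and strongly suppressed while the optode is displaced by
        # motion (that is what makes the segment low-quality, not the
        # spikes themselves, which the cardiac band-pass largely removes)
        envelope = 1.0 + 0.2 * np.sin(2.0 * np.pi * 0.02 * t + rng.uniform(0, 2 * np.pi))
        gate = np.ones(n)
        motion_spans: dict[int, tuple[int, int]] = {}
        for k, mode in enumerate(plan):
            if mode == "coupling_loss":
                gate[k * seg_len : (k + 1) * seg_len] = 0.0
            elif mode == "motion_burst":
                a, b = k * seg_len, (k + 1) * seg_len
                span_len = int((b - a) * rng.uniform(0.6, 0.9))
                start = a + int(rng.uniform(0, (b - a) - span_len))
                motion_spans[k] = (start, start + span_len)
                gate[start : start + span_len] = 0.1
        phase = rng.uniform(0, 2 * np.pi)
        fundamental = np.sin(2.0 * np.pi * hr * t + phase)
        # second harmonic only when it stays below Nyquist
        if 2.0 * hr < cfg.fs / 2.0:
            fundamental = fundamental + 0.2 * np.sin(2.0 * np.pi * 2.0 * hr * t + 2.0 * phase)
        cardiac = cfg.cardiac_amplitude_um * envelope * gate * fundamental
        hbo = (
            cardiac
            + cfg.mayer_amplitude_um * np.sin(2.0 * np.pi * cfg.mayer_freq_hz * t + rng.uniform(0, 2 * np.pi))
            + cfg.resp_amplitude_um * np.sin(2.0 * np.pi * cfg.resp_freq_hz * t + rng.uniform(0, 2 * np.pi))
            + cfg.drift_scale_um * _one_over_f_noise(rng, n, cfg.fs, cfg.drift_exponent)
        )
        hbr = cfg.hbr_ratio * hbo + 0.05 * cfg.cardiac_amplitude_um * rng.standard_normal(n)
        hbo_truth[:, ch] = hbo
        od = forward_mbll(hbo[:, None], hbr[:, None], replace(
            params, separation_cm=params.separation_cm[ch : ch + 1]
        ))[:, 0, :]

        for k, mode in enumerate(plan):
            a, b = k * seg_len, (k + 1) * seg_len
            ref = SegmentRef(subject_id, ch, k, a, b)
            spans: list[ArtifactSpan] = []
            if mode == "coupling_loss":
                od[a:b, :] += 0.25 * rng.standard_normal((b - a, 2))
                spans.append(ArtifactSpan("coupling_loss", a, b))
            elif mode == "motion_burst":
                start, stop = motion_spans[k]
                span_len = stop - start
                for _ in range(rng.integers(4, 9)):
                    pos = int(rng.uniform(start, stop - 2))
                    width = int(rng.integers(2, max(3, int(0.5 * cfg.fs))))
                    od[pos : pos + width, :] += rng.uniform(0.05, 0.2) * rng.choice([-1.0, 1.0])
                step_at = start + span_len // 2
                od[step_at:b, :] += rng.uniform(0.02, 0.08) * rng.choice([-1.0, 1.0])
                spans.append(ArtifactSpan("motion_burst", start, stop))
            labels[ref] = "low" if mode is not None else "high"
            artifacts[ref] = spans

        chan_intensity = cfg.i0 * np.exp(-od)
        chan_intensity += cfg.noise_sd * cfg.i0 * rng.standard_normal((n, 2))
        # saturation overrides everything: constant clipped intensity
        for k, mode in enumerate(plan):
            if mode == "saturation":
                a, b = k * seg_len, (k + 1) * seg_len
                chan_intensity[a:b, :] = cfg.i0 * 1.05
                artifacts[SegmentRef(subject_id, ch, k, a, b)].append(
                    ArtifactSpan("saturation", a, b)
                )
        intensity[:, ch, :] = np.maximum(chan_intensity, 1e-6)

    # trailing remainder samples carry signal but belong to no segment
    rec = Recording(
        subject_id=subject_id,
        intensity=intensity,
        fs=cfg.fs,
        montage=montage,
    )
    truth = GroundTruth(
        labels=labels,
        heart_rates={subject_id: hr},
        artifacts=artifacts,
        hbo={subject_id: hbo_truth},
    )
    return rec, truth


def simulate_dataset(
    cfg: SimConfig, out_dir: str | Path | None = None, format: str = "snirf"
) -> tuple[list[Recording], GroundTruth, pd.DataFrame]:
    """Simulate a cohort; optionally write fixture files plus a label CSV."""
    cfg.validate()
    recordings: list[Recording] = []
    labels: dict[SegmentRef, str] = {}
    heart_rates: dict[str, float] = {}
    artifacts: dict[SegmentRef, list[ArtifactSpan]] = {}
    hbo: dict[str, np.ndarray] = {}
    for i in range(cfg.n_subjects):
        rec, truth = simulate_recording(cfg, i)
        recordings.append(rec)
        labels.update(truth.labels)
        heart_rates.update(truth.heart_rates)
        artifacts.update(truth.artifacts)
        hbo.update(truth.hbo)
    truth = GroundTruth(labels=labels, heart_rates=heart_rates, artifacts=artifacts, hbo=hbo)
    frame = truth.label_frame()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            if format == "snirf":
                signal_io.write_snirf(rec, out_dir / f"{rec.subject_id}.snirf")
            elif format == "nirs":
                signal_io.write_nirs_mat(rec, out_dir / f"{rec.subject_id}.nirs")
            else:
                raise ValueError(f"unknown fixture format: {format!r}")
        signal_io.write_labels(frame, out_dir / "labels.csv")
    return recordings, truth, frame


def truth_segments(rec: Recording, cfg: SimConfig) -> list[SegmentRef]:
    """The segment grid the simulator labeled (matches segment_channels)."""
    return segment_channels(rec, cfg.n_segments)
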