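"""Reading and writing of fNIRS recordings, labels and quality reports.

Supported formats:

* a minimal continuous-wave SNIRF dialect (``.snirf``, HDF5): only
  ``/nirs/data1/dataTimeSeries``, the ``measurementList`` entries and the
  probe geometry are interpreted; every other block is ignored with a
  logged warning;
* Homer-style ``.nirs``/``.mat`` files (MATLAB v5) with mandatory fields
  ``d`` and ``SD.MeasList`` and optional ``t``, ``s``, ``aux``, ``age``.
  The field ``d`` is treated as *raw light intensity* (the ``.nirs``
  convention), which is the quantity the pipeline starts from;
* CSV label files with columns ``subject,channel,segment,label`` and
  CSV/JSON quality reports.

All sample intervals are 0-based and half-open.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

logger = logging.getLogger(__name__)

DEFAULT_WAVELENGTHS = (760.0, 850.0)

#: source-detector separations below this are treated as short channels (mm)
SHORT_SEPARATION_MM = 15.0


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass(frozen=True)
class ChannelGeometry:
    """One optode pair of the montage."""

    source: int
    detector: int
    separation_mm: float
    is_short: bool


@dataclass
class Recording:
    """A dual-wavelength raw light-intensity recording.

    Attributes
    ----------
    intensity : ndarray, shape (time, channel, 2)
        Strictly positive light intensity in arbitrary units.
    fs : float
        Sampling rate in Hz.
    wavelengths : tuple of float
        The two nominal wavelengths in nm.
    montage : list of ChannelGeometry
        One entry per channel.
    age : float or None
        Subject age in years, if known.
    events : ndarray or None
        Optional sparse event markers (time, value).
    """

    subject_id: str
    intensity: np.ndarray
    fs: float
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    montage: list[ChannelGeometry] = field(default_factory=list)
    age: float | None = None
    events: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise ValueError(
                f"intensity must have shape (time, channel, 2), got {self.intensity.shape}"
            )
        if not np.all(np.isfinite(self.intensity)):
            bad = np.argwhere(~np.isfinite(self.intensity))[0]
            raise FormatError(
                f"non-finite intensity at sample={bad[0]}, channel={bad[1]}, wavelength={bad[2]}"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.wavelengths) != 2:
            raise ValueError("exactly two wavelengths are required")
        if self.montage and len(self.montage) != self.intensity.shape[1]:
            raise ValueError("montage length does not match channel count")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True, order=True)
class SegmentRef:
    """Half-open sample interval of one channel of one subject."""

    subject_id: str
    channel_index: int
    segment_index: int
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.end_sample <= self.start_sample:
            raise ValueError("end_sample must exceed start_sample")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class SegmentPrediction:
    ref: SegmentRef
    label: str  # "high" | "low"
    p_low: float


@dataclass
class QualityReport:
    """Per-segment predictions plus per-channel quality percentages."""

    subject_id: str
    segments: list[SegmentPrediction]

    def channel_percentages(self) -> dict[int, float]:
        """Percentage of segments predicted high per channel.

        Computed with exact rational arithmetic before conversion to
        float, so 3 high out of 5 is exactly 60.0.
        """
        by_channel: dict[int, list[SegmentPrediction]] = {}
        for seg in self.segments:
            by_channel.setdefault(seg.ref.channel_index, []).append(seg)
        out: dict[int, float] = {}
        for ch, segs in sorted(by_channel.items()):
            n_high = sum(1 for s in segs if s.label == "high")
            out[ch] = float(Fraction(100 * n_high, len(segs)))
        return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_channels(rec: Recording, n_segments: int) -> list[SegmentRef]:
    """Split every channel into equal, contiguous, non-overlapping segments.

    Remainder samples (fewer than ``n_segments``) are dropped from the end
    of the recording. Returns ``n_channels * n_segments`` refs.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    seg_len = rec.n_samples // n_segments
    if seg_len < 1:
        raise ValueError(
            f"record too short: {rec.n_samples} samples cannot form {n_segments} segments"
        )
    refs = []
    for ch in range(rec.n_channels):
        for k in range(n_segments):
            refs.append(
                SegmentRef(
                    subject_id=rec.subject_id,
                    channel_index=ch,
                    segment_index=k,
                    start_sample=k * seg_len,
                    end_sample=(k + 1) * seg_len,
                )
            )
    return refs


# ---------------------------------------------------------------------------
# SNIRF
# ---------------------------------------------------------------------------

_KNOWN_NIRS_KEYS = {"data1", "probe", "metaDataTags"}


def write_snirf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as a minimal continuous-wave SNIRF v1 file."""
    path = Path(path)
    n_t, n_ch, _ = rec.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        # column order: (channel 0, wl 0), (channel 0, wl 1), (channel 1, wl 0), ...
        flat = rec.intensity.reshape(n_t, n_ch * 2)
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(n_t) / rec.fs)
        montage = rec.montage or _default_montage(n_ch)
        for ch in range(n_ch):
            for wl in range(2):
                ml = data.create_group(f"measurementList{ch * 2 + wl + 1}")
                ml.create_dataset("sourceIndex", data=montage[ch].source + 1)
                ml.create_dataset("detectorIndex", data=montage[ch].detector + 1)
                ml.create_dataset("wavelengthIndex", data=wl + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
        src_pos, det_pos = _montage_positions(montage)
        probe.create_dataset("sourcePos2D", data=src_pos)
        probe.create_dataset("detectorPos2D", data=det_pos)
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("LengthUnit", data="mm")
        if rec.age is not None:
            meta.create_dataset("Age", data=float(rec.age))


def read_snirf(path: str | Path, fs: float | None = None) -> Recording:
    """Read the minimal SNIRF dialect written by :func:`write_snirf`.

    Measurements are grouped so that each (source, detector) pair yields
    one channel with both wavelength columns. The sampling rate is derived
    from the time vector unless ``fs`` is supplied.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise FormatError("missing mandatory group /nirs")
        nirs = f["nirs"]
        if "data1" not in nirs:
            raise FormatError("missing mandatory group /nirs/data1")
        data = nirs["data1"]
        if "dataTimeSeries" not in data:
            raise FormatError("missing mandatory dataset /nirs/data1/dataTimeSeries")
        ts = np.asarray(data["dataTimeSeries"], dtype=float)
        for key in nirs:
            if key not in _KNOWN_NIRS_KEYS:
                logger.warning("ignoring unsupported SNIRF block /nirs/%s", key)
        ml_names = sorted(
            (k for k in data if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if len(ml_names) != ts.shape[1]:
            raise FormatError(
                f"{len(ml_names)} measurementList entries but {ts.shape[1]} data columns"
            )
        measurements = []
        for col, name in enumerate(ml_names):
            ml = data[name]
            measurements.append(
                (
                    int(np.asarray(ml["sourceIndex"])),
                    int(np.asarray(ml["detectorIndex"])),
                    int(np.asarray(ml["wavelengthIndex"])),
                    col,
                )
            )
        if fs is None:
            if "time" not in data:
                raise FormatError("missing /nirs/data1/time and no fs supplied")
            t = np.asarray(data["time"], dtype=float)
            if t.size < 2:
                raise FormatError("time vector too short to derive sampling rate")
            fs = 1.0 / float(np.median(np.diff(t)))

        wavelengths = DEFAULT_WAVELENGTHS
        src_pos = det_pos = None
        if "probe" in nirs:
            probe = nirs["probe"]
            if "wavelengths" in probe:
                wl = np.asarray(probe["wavelengths"], dtype=float).ravel()
                if wl.size >= 2:
                    wavelengths = (float(wl[0]), float(wl[1]))
            for key, target in (("sourcePos2D", "s"), ("sourcePos3D", "s")):
                if key in probe and src_pos is None:
                    src_pos = np.asarray(probe[key], dtype=float)
            for key in ("detectorPos2D", "detectorPos3D"):
                if key in probe and det_pos is None:
                    det_pos = np.asarray(probe[key], dtype=float)

        subject_id = path.stem
        age = None
        if "metaDataTags" in nirs:
            meta = nirs["metaDataTags"]
            if "SubjectID" in meta:
                raw = meta["SubjectID"][()]
                subject_id = raw.decode() if isinstance(raw, bytes) else str(raw)
            if "Age" in meta:
                age = float(np.asarray(meta["Age"]))

    intensity, montage = _group_measurements(ts, measurements, src_pos, det_pos)
    return Recording(
        subject_id=subject_id,
        intensity=intensity,
        fs=float(fs),
        wavelengths=wavelengths,
        montage=montage,
        age=age,
    )


def _group_measurements(ts, measurements, src_pos, det_pos):
    pairs: dict[tuple[int, int], dict[int, int]] = {}
    for src, det, wl_idx, col in measurements:
        pairs.setdefault((src, det), {})[wl_idx] = col
    channels = sorted(pairs)
    n_t = ts.shape[0]
    intensity = np.empty((n_t, len(channels), 2))
    montage = []
    for ch, (src, det) in enumerate(channels):
        cols = pairs[(src, det)]
        if set(cols) != {1, 2}:
            raise FormatError(
                f"channel source={src} detector={det} lacks a second wavelength"
            )
        intensity[:, ch, 0] = ts[:, cols[1]]
        intensity[:, ch, 1] = ts[:, cols[2]]
        sep = 30.0
        if src_pos is not None and det_pos is not None:
            try:
                sep = float(np.linalg.norm(src_pos[src - 1] - det_pos[det - 1]))
            except IndexError:
                pass
        montage.append(
            ChannelGeometry(src - 1, det - 1, sep, sep < SHORT_SEPARATION_MM)
        )
    return intensity, montage


def _default_montage(n_channels: int) -> list[ChannelGeometry]:
    return [ChannelGeometry(i, i, 30.0, False) for i in range(n_channels)]


def _montage_positions(montage: Sequence[ChannelGeometry]):
    n_src = max(g.source for g in montage) + 1
    n_det = max(g.detector for g in montage) + 1
    src_pos = np.zeros((n_src, 2))
    det_pos = np.zeros((n_det, 2))
    for i, g in enumerate(montage):
        src_pos[g.source] = (0.0, 40.0 * i)
        det_pos[g.detector] = (g.separation_mm, 40.0 * i)
    return src_pos, det_pos


# ---------------------------------------------------------------------------
# Homer-style .nirs / .mat
# ---------------------------------------------------------------------------


def write_nirs_mat(rec: Recording, path: str | Path) -> None:
    """Write a Recording as a Homer-style .nirs/.mat file (MATLAB v5)."""
    n_t, n_ch, _ = rec.intensity.shape
    montage = rec.montage or _default_montage(n_ch)
    # MeasList rows: source, detector, 1, wavelengthIndex; wavelength-major
    # blocks as Homer writes them (all wl-1 columns, then all wl-2 columns).
    meas_list = []
    for wl in (1, 2):
        for g in montage:
            meas_list.append([g.source + 1, g.detector + 1, 1, wl])
    d = np.concatenate([rec.intensity[:, :, 0], rec.intensity[:, :, 1]], axis=1)
    src_pos, det_pos = _montage_positions(montage)
    sd = {
        "MeasList": np.asarray(meas_list, dtype=float),
        "Lambda": np.asarray(rec.wavelengths, dtype=float),
        "SrcPos": src_pos,
        "DetPos": det_pos,
        "SpatialUnit": "mm",
    }
    mat: dict[str, object] = {
        "d": d,
        "SD": sd,
        "t": np.arange(n_t) / rec.fs,
        "s": np.zeros((n_t, 1)),
        "aux": np.zeros((n_t, 1)),
    }
    if rec.age is not None:
        mat["age"] = float(rec.age)
    savemat(str(path), mat)


def read_nirs_mat(path: str | Path, fs: float | None = None) -> Recording:
    """Read a Homer-style .nirs/.mat file.

    ``d`` is interpreted as raw light intensity. Columns are paired into
    channels via the MeasList wavelength index. ``fs`` overrides the rate
    derived from the time vector ``t``.
    """
    path = Path(path)
    try:
        mat = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if "d" not in mat:
        raise FormatError("missing mandatory field d")
    if "SD" not in mat:
        raise FormatError("missing mandatory field SD")
    d = np.atleast_2d(np.asarray(mat["d"], dtype=float))
    sd = mat["SD"]
    try:
        meas_list = np.atleast_2d(np.asarray(sd.MeasList, dtype=float))
    except AttributeError as exc:
        raise FormatError("SD struct lacks MeasList") from exc
    if meas_list.shape[0] != d.shape[1]:
        raise FormatError(
            f"d has {d.shape[1]} columns but MeasList {meas_list.shape[0]} rows"
        )
    src_pos = getattr(sd, "SrcPos", None)
    det_pos = getattr(sd, "DetPos", None)
    if src_pos is not None:
        src_pos = np.atleast_2d(np.asarray(src_pos, dtype=float))
    if det_pos is not None:
        det_pos = np.atleast_2d(np.asarray(det_pos, dtype=float))
    wavelengths = DEFAULT_WAVELENGTHS
    lam = getattr(sd, "Lambda", None)
    if lam is not None:
        lam = np.asarray(lam, dtype=float).ravel()
        if lam.size >= 2:
            wavelengths = (float(lam[0]), float(lam[1]))
    if fs is None:
        t = mat.get("t")
        if t is None:
            raise FormatError("no sampling rate supplied and no time vector t")
        t = np.asarray(t, dtype=float).ravel()
        if t.size < 2:
            raise FormatError("time vector too short to derive sampling rate")
        fs = 1.0 / float(np.median(np.diff(t)))
    measurements = [
        (int(row[0]), int(row[1]), int(row[3]), col)
        for col, row in enumerate(meas_list)
    ]
    intensity, montage = _group_measurements(d, measurements, src_pos, det_pos)
    age = mat.get("age")
    if age is not None:
        age = float(np.asarray(age).ravel()[0])
    return Recording(
        subject_id=path.stem,
        intensity=intensity,
        fs=float(fs),
        wavelengths=wavelengths,
        montage=montage,
        age=age,
    )


def read_recording(path: str | Path, fs: float | None = None) -> Recording:
    """Dispatch on file extension (.snirf vs .nirs/.mat)."""
    path = Path(path)
    if path.suffix.lower() == ".snirf":
        return read_snirf(path, fs=fs)
    if path.suffix.lower() in {".nirs", ".mat"}:
        return read_nirs_mat(path, fs=fs)
    raise FormatError(f"unrecognized recording extension: {path.suffix}")


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

LABEL_COLUMNS = ["subject", "channel", "segment", "label"]


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    """Write a label table (columns subject, channel, segment, label)."""
    df = labels[LABEL_COLUMNS].sort_values(LABEL_COLUMNS[:3], kind="mergesort")
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject": str, "channel": int, "segment": int, "label": str})
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"label file missing columns: {sorted(missing)}")
    bad = set(df["label"]) - {"high", "low"}
    if bad:
        raise FormatError(f"unknown labels: {sorted(bad)}")
    return df[LABEL_COLUMNS]


def merge_label_sets(*label_sets: pd.DataFrame) -> pd.DataFrame:
    """Concatenate labeled segment collections into one dataset."""
    if not label_sets:
        raise ValueError("at least one label set is required")
    return pd.concat(label_sets, ignore_index=True)[LABEL_COLUMNS]


def summarize_labels(labels: pd.DataFrame) -> dict[str, float]:
    """Class counts and percentages of a labeled segment collection.

    Percentages are computed with exact rational arithmetic and rounded
    to one decimal, matching how class shares are conventionally printed.
    """
    n = len(labels)
    n_low = int((labels["label"] == "low").sum())
    n_high = int((labels["label"] == "high").sum())
    if n_low + n_high != n:
        raise ValueError("labels must all be 'high' or 'low'")
    pct = lambda k: round(float(Fraction(100 * k, n)), 1) if n else math.nan
    return {
        "n_total": n,
        "n_low": n_low,
        "n_high": n_high,
        "pct_low": pct(n_low),
        "pct_high": pct(n_high),
    }


# ---------------------------------------------------------------------------
# quality reports
# ---------------------------------------------------------------------------


def write_quality_report(report: QualityReport, path: str | Path, format: str = "csv") -> None:
    """Serialize a quality report: segment rows, then channel summary rows.

    The row order and column order are deterministic so identical reports
    serialize byte-identically.
    """
    path = Path(path)
    segs = sorted(report.segments, key=lambda s: (s.ref.channel_index, s.ref.segment_index))
    channel_pct = report.channel_percentages()
    if format == "csv":
        rows = []
        for s in segs:
            rows.append(
                {
                    "record_type": "segment",
                    "subject": s.ref.subject_id,
                    "channel": s.ref.channel_index,
                    "segment": s.ref.segment_index,
                    "start_sample": s.ref.start_sample,
                    "end_sample": s.ref.end_sample,
                    "label": s.label,
                    "p_low": repr(float(s.p_low)),
                    "quality_pct": "",
                }
            )
        for ch, pct in channel_pct.items():
            rows.append(
                {
                    "record_type": "channel",
                    "subject": report.subject_id,
                    "channel": ch,
                    "segment": "",
                    "start_sample": "",
                    "end_sample": "",
                    "label": "",
                    "p_low": "",
                    "quality_pct": repr(float(pct)),
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "record_type", "subject", "channel", "segment",
                "start_sample", "end_sample", "label", "p_low", "quality_pct",
            ],
        ).to_csv(path, index=False)
    elif format == "json":
        payload = {
            "subject": report.subject_id,
            "segments": [
                {
                    "channel": s.ref.channel_index,
                    "segment": s.ref.segment_index,
                    "start_sample": s.ref.start_sample,
                    "end_sample": s.ref.end_sample,
                    "label": s.label,
                    "p_low": float(s.p_low),
                }
                for s in segs
            ],
            "channel_quality_pct": {str(ch): pct for ch, pct in channel_pct.items()},
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_quality_report(path: str | Path) -> QualityReport:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        segs = [
            SegmentPrediction(
                ref=SegmentRef(
                    subject_id=payload["subject"],
                    channel_index=int(d["channel"]),
                    segment_index=int(d["segment"]),
                    start_sample=int(d["start_sample"]),
                    end_sample=int(d["end_sample"]),
                ),
                label=d["label"],
                p_low=float(d["p_low"]),
            )
            for d in payload["segments"]
        ]
        return QualityReport(subject_id=payload["subject"], segments=segs)
    df = pd.read_csv(path, dtype={"record_type": str, "subject": str})
    seg_rows = df[df["record_type"] == "segment"]
    segs = [
        SegmentPrediction(
            ref=SegmentRef(
                subject_id=str(row["subject"]),
                channel_index=int(row["channel"]),
                segment_index=int(row["segment"]),
                start_sample=int(row["start_sample"]),
                end_sample=int(row["end_sample"]),
            ),
            label=str(row["label"]),
            p_low=float(row["p_low"]),
        )
        for _, row in seg_rows.iterrows()
    ]
    subject = str(df["subject"].iloc[0]) if len(df) else ""
    return QualityReport(subject_id=subject, segments=segs)
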