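"""Convenience composition of the full preprocessing chain.

Wires intensity -> hemoglobin -> subject band -> standardized scalogram
images for whole recordings; used by the CLI, the test harness and the
acceptance script.
"""

from __future__ import annotations

from nirsqc.cardiac_band import CardiacBand, fit_subject_band
from nirsqc.classifier import LabeledSample
from nirsqc.hemodynamics import recording_to_hb
from nirsqc.scalogram import StandardizedImage, segment_scalograms
from nirsqc.signal_io import Recording, segment_channels
from nirsqc.synthetic import GroundTruth


def quality_images(
    rec: Recording, n_segments: int, band: CardiacBand | None = None
) -> list[StandardizedImage]:
    """Standardized scalogram images for every segment of a recording."""
    if band is None:
        band = fit_subject_band(rec)
    hb = recording_to_hb(rec)
    by_channel: dict[int, list] = {}
    for ref in segment_channels(rec, n_segments):
        by_channel.setdefault(ref.channel_index, []).append(ref)
    images: list[StandardizedImage] = []
    for ch, refs in sorted(by_channel.items()):
        images.extend(segment_scalograms(hb.hbo[:, ch], rec.fs, band, refs))
    return images


def labeled_samples(
    recordings: list[Recording], truth: GroundTruth, n_segments: int
) -> list[LabeledSample]:
    """Images plus simulator ground-truth labels for a whole cohort."""
    samples: list[LabeledSample] = []
    for rec in recordings:
        for img in quality_images(rec, n_segments):
            ref = img.provenance
            samples.append(
                LabeledSample(
                    image=img.pixels,
                    label=truth.labels[ref],
                    subject_id=ref.subject_id,
                    channel_index=ref.channel_index,
                    segment_index=ref.segment_index,
                )
            )
    return samples
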