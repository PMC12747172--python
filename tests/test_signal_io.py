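import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsqc import signal_io
from nirsqc.signal_io import (
    FormatError,
    QualityReport,
    Recording,
    SegmentPrediction,
    SegmentRef,
    merge_label_sets,
    read_nirs_mat,
    read_snirf,
    segment_channels,
    summarize_labels,
    write_nirs_mat,
    write_snirf,
)
from nirsqc.synthetic import SimConfig, simulate_recording


class TestSnirf:
    def test_round_trip_minimal(self, small_recording, tmp_path):
        path = tmp_path / "rec.snirf"
        write_snirf(small_recording, path)
        rec = read_snirf(path)
        assert rec.intensity.shape == (100, 2, 2)
        np.testing.assert_allclose(rec.intensity, small_recording.intensity, rtol=1e-12)
        assert rec.subject_id == "sub01"
        assert rec.age == 30.0
        assert rec.fs == pytest.approx(7.812, rel=1e-9)
        assert [g.separation_mm for g in rec.montage] == pytest.approx([30.0, 8.0])
        assert [g.is_short for g in rec.montage] == [False, True]

    def test_single_wavelength_pair_is_format_error(self, small_recording, tmp_path):
        import h5py

        path = tmp_path / "broken.snirf"
        write_snirf(small_recording, path)
        with h5py.File(path, "a") as f:
            data = f["nirs/data1"]
            ts = data["dataTimeSeries"][:, :3]
            del data["dataTimeSeries"]
            data.create_dataset("dataTimeSeries", data=ts)
            del data["measurementList4"]
        with pytest.raises(FormatError, match="wavelength"):
            read_snirf(path)

    def test_missing_group_names_path(self, tmp_path):
        import h5py

        path = tmp_path / "empty.snirf"
        with h5py.File(path, "w") as f:
            f.create_group("nirs")
        with pytest.raises(FormatError, match="/nirs/data1"):
            read_snirf(path)

    def test_synthetic_fixture_fs_round_trip(self, tmp_path):
        cfg = SimConfig(n_subjects=1, n_channels=2, duration_s=30, fs=7.812, seed=3)
        rec, _ = simulate_recording(cfg, 0)
        path = tmp_path / "sim.snirf"
        write_snirf(rec, path)
        assert read_snirf(path).fs == pytest.approx(7.812, rel=1e-9)


class TestNirsMat:
    def test_round_trip(self, small_recording, tmp_path):
        path = tmp_path / "rec.nirs"
        write_nirs_mat(small_recording, path)
        rec = read_nirs_mat(path)
        np.testing.assert_allclose(rec.intensity, small_recording.intensity, rtol=1e-12)
        assert rec.age == 30.0
        assert rec.fs == pytest.approx(7.812, rel=1e-9)
        assert [g.separation_mm for g in rec.montage] == pytest.approx([30.0, 8.0])

    def test_28_channel_fixture(self, rng, tmp_path):
        intensity = 1.0 + 0.05 * rng.random((50, 28, 2))
        rec = Recording(subject_id="s", intensity=intensity, fs=7.812)
        path = tmp_path / "big.nirs"
        write_nirs_mat(rec, path)
        assert read_nirs_mat(path).n_channels == 28

    def test_missing_sd_is_format_error(self, tmp_path):
        from scipy.io import savemat

        path = tmp_path / "nosd.mat"
        savemat(str(path), {"d": np.ones((10, 4))})
        with pytest.raises(FormatError, match="SD"):
            read_nirs_mat(path, fs=8.0)

    def test_age_field(self, small_recording, tmp_path):
        path = tmp_path / "aged.nirs"
        write_nirs_mat(small_recording, path)
        assert read_nirs_mat(path).age == 30.0

    def test_meas_list_mismatch(self, small_recording, tmp_path):
        from scipy.io import loadmat, savemat

        path = tmp_path / "rec.mat"
        write_nirs_mat(small_recording, path)
        mat = loadmat(str(path))
        mat["d"] = mat["d"][:, :3]
        savemat(str(path), mat)
        with pytest.raises(FormatError, match="columns"):
            read_nirs_mat(path, fs=8.0)


class TestSegmentChannels:
    def test_printed_dataset_structure(self, rng):
        total = 0
        for i in range(40):
            rec = Recording(
                subject_id=f"s{i}",
                intensity=1.0 + rng.random((50, 28, 2)),
                fs=7.812,
            )
            total += len(segment_channels(rec, 5))
        assert total == 5600

    def test_segment_duration_356s(self, rng):
        fs = 7.812
        n = int(round(1780 * fs))
        rec = Recording(subject_id="s", intensity=1.0 + rng.random((n, 1, 2)), fs=fs)
        refs = segment_channels(rec, 5)
        durations = {r.n_samples / fs for r in refs}
        assert len(durations) == 1
        assert durations.pop() == pytest.approx(356.0, abs=1.0 / fs)

    def test_single_segment(self, rng):
        rec = Recording(subject_id="s", intensity=1.0 + rng.random((10, 1, 2)), fs=1.0)
        (ref,) = segment_channels(rec, 1)
        assert (ref.start_sample, ref.end_sample) == (0, 10)

    def test_too_short_errors(self, rng):
        rec = Recording(subject_id="s", intensity=1.0 + rng.random((3, 1, 2)), fs=1.0)
        with pytest.raises(ValueError, match="too short"):
            segment_channels(rec, 5)

    @given(n_samples=st.integers(10, 500), n_segments=st.integers(1, 9))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, n_samples, n_segments):
        rec = Recording(
            subject_id="s",
            intensity=np.ones((n_samples, 1, 2)),
            fs=1.0,
        )
        refs = segment_channels(rec, n_segments)
        assert len(refs) == n_segments
        seg_len = n_samples // n_segments
        assert refs[0].start_sample == 0
        assert refs[-1].end_sample == n_segments * seg_len
        for a, b in zip(refs, refs[1:]):
            assert a.end_sample == b.start_sample


class TestLabels:
    def test_summary_and_merge(self):
        ds1 = pd.DataFrame(
            {
                "subject": ["a"] * 5600,
                "channel": [0] * 5600,
                "segment": range(5600),
                "label": ["low"] * 3347 + ["high"] * 2253,
            }
        )
        summary = summarize_labels(ds1)
        assert summary["pct_low"] == 59.8
        ds2 = pd.DataFrame(
            {
                "subject": ["b"] * 5060,
                "channel": [0] * 5060,
                "segment": range(5060),
                "label": ["high"] * 3227 + ["low"] * 1833,
            }
        )
        assert summarize_labels(ds2)["pct_high"] == 63.8
        merged = merge_label_sets(ds1, ds2)
        combined = summarize_labels(merged)
        assert combined["n_total"] == 10660
        assert combined["n_high"] == 5480
        assert combined["pct_high"] == 51.4

    def test_label_file_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "subject": ["s1", "s1", "s2"],
                "channel": [0, 1, 0],
                "segment": [0, 0, 2],
                "label": ["high", "low", "high"],
            }
        )
        path = tmp_path / "labels.csv"
        signal_io.write_labels(df, path)
        back = signal_io.read_labels(path)
        pd.testing.assert_frame_equal(
            back.sort_values(["subject", "channel", "segment"]).reset_index(drop=True),
            df.sort_values(["subject", "channel", "segment"]).reset_index(drop=True),
        )

    def test_bad_label_rejected(self, tmp_path):
        path = tmp_path / "labels.csv"
        path.write_text("subject,channel,segment,label\ns1,0,0,medium\n")
        with pytest.raises(FormatError, match="medium"):
            signal_io.read_labels(path)


def _make_report(labels):
    segs = [
        SegmentPrediction(
            ref=SegmentRef("s", 0, k, k * 10, (k + 1) * 10),
            label=lab,
            p_low=0.2 if lab == "high" else 0.8,
        )
        for k, lab in enumerate(labels)
    ]
    return QualityReport(subject_id="s", segments=segs)


class TestQualityReport:
    def test_channel_percentage_60(self):
        report = _make_report(["high", "high", "high", "low", "low"])
        assert report.channel_percentages() == {0: 60.0}

    def test_empty_report_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        signal_io.write_quality_report(QualityReport("s", []), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("record_type,")

    @pytest.mark.parametrize("fmt,suffix", [("csv", ".csv"), ("json", ".json")])
    def test_round_trip(self, tmp_path, fmt, suffix):
        report = _make_report(["high", "low", "high"])
        path = tmp_path / f"report{suffix}"
        signal_io.write_quality_report(report, path, format=fmt)
        back = signal_io.read_quality_report(path)
        assert back.subject_id == "s"
        assert [s.label for s in back.segments] == ["high", "low", "high"]
        assert [s.p_low for s in back.segments] == [0.2, 0.8, 0.2]
        assert back.channel_percentages() == report.channel_percentages()

    @given(st.lists(st.sampled_from(["high", "low"]), min_size=1, max_size=30))
    @settings(max_examples=40, deadline=None)
    def test_percentage_matches_direct_count(self, labels):
        report = _make_report(labels)
        expected = 100.0 * labels.count("high") / len(labels)
        assert report.channel_percentages()[0] == pytest.approx(expected, abs=1e-12)


def test_nonfinite_intensity_rejected():
    intensity = np.ones((10, 1, 2))
    intensity[3, 0, 1] = np.nan
    with pytest.raises(FormatError, match="non-finite"):
        Recording(subject_id="s", intensity=intensity, fs=1.0)
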