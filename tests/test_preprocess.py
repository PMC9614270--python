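"""Cleaning chain: amplitude mask, re-referencing, band-pass,
segmentation, z-scoring and the patient inclusion rule."""

import numpy as np
import pytest

from podeeg.config import PipelineConfig
from podeeg.errors import ConfigError, ContractError, DegenerateInputError, InputError
from podeeg.preprocess import (
    EEGRecording,
    Segment,
    SegmentSeries,
    amplitude_artifact_mask,
    bandpass,
    common_average_reference,
    dilate_mask,
    passes_inclusion,
    preprocess_recording,
    segment,
    zscore_segments,
)
from podeeg.simulate import CohortSpec, simulate_eeg

FS = 128.0


def _rec(signal, fs=FS):
    return EEGRecording(np.atleast_2d(signal), fs)


class TestAmplitudeMask:
    def test_sinusoid_flags_only_top_percent_near_peaks(self):
        t = np.arange(0, 100, 1 / FS)
        x = np.sin(2 * np.pi * (np.pi / 3) * t)   # non-commensurate frequency
        mask = amplitude_artifact_mask(_rec(np.tile(x, (4, 1))))
        assert mask.mean() == pytest.approx(0.01, abs=0.002)
        assert np.abs(x[mask]).min() > np.quantile(np.abs(x), 0.98)

    def test_quantile_near_one_gives_empty_mask(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.normal(size=(4, 1000)))
        # in the limit only the single maximal sample can remain flagged
        assert amplitude_artifact_mask(rec, quantile=1 - 1e-12).sum() <= 1

    def test_flagged_fraction_bounded_by_channel_count(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.normal(size=(4, 20000)))
        mask = amplitude_artifact_mask(rec, 0.99)
        assert mask.mean() <= 0.01 * 4 + 1e-9

    def test_planted_spikes_are_flagged(self):
        spec = CohortSpec(n_patients=1, artifact_rate_per_min=1.0, seed=0)
        rec, truth = simulate_eeg(
            0, "Propofol", spec, np.random.default_rng(7), duration_s=1500
        )
        mask = dilate_mask(amplitude_artifact_mask(rec), FS, 0.1)
        assert mask[truth.artifact_indices].mean() >= 0.95

    def test_bad_quantile_rejected(self):
        rec = _rec(np.ones((4, 10)))
        for q in (0.0, 1.0, 1.5):
            with pytest.raises(ConfigError):
                amplitude_artifact_mask(rec, q)


class TestCommonAverageReference:
    def test_opposite_channels_unchanged(self):
        x = np.vstack([np.sin(np.linspace(0, 10, 500)), -np.sin(np.linspace(0, 10, 500))])
        out = common_average_reference(_rec(x))
        np.testing.assert_allclose(out.signal, x, atol=1e-12)

    def test_constant_offset_removed_and_column_means_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 1000)) + 17.0
        out = common_average_reference(_rec(x))
        assert np.abs(out.signal.mean(axis=0)).max() < 1e-12

    def test_single_channel_rejected(self):
        with pytest.raises(ContractError):
            common_average_reference(_rec(np.ones((1, 10))))


class TestBandpass:
    def test_passband_preserved(self):
        t = np.arange(0, 20, 1 / FS)
        rec = _rec(np.tile(np.sin(2 * np.pi * 10 * t), (4, 1)))
        y = bandpass(rec).signal[0][5 * int(FS) : 15 * int(FS)]
        assert np.sqrt(2) * y.std() == pytest.approx(1.0, rel=0.05)

    def test_60hz_attenuated(self):
        fs = 256.0
        t = np.arange(0, 20, 1 / fs)
        rec = _rec(np.tile(np.sin(2 * np.pi * 60 * t), (4, 1)), fs)
        y = bandpass(rec).signal[0][5 * int(fs) : 15 * int(fs)]
        assert np.sqrt(2) * y.std() < 0.10

    def test_dc_removed(self):
        rec = _rec(np.full((4, 4000), 5.0))
        assert np.abs(bandpass(rec).signal[:, 1000:3000]).max() < 1e-6

    def test_edge_above_nyquist_rejected(self):
        rec = _rec(np.ones((4, 1000)), fs=64.0)
        with pytest.raises(ConfigError):
            bandpass(rec, high=50.0)


class TestSegmentation:
    def test_clean_recording_padded_at_edges(self):
        rec = _rec(np.random.default_rng(0).normal(size=(4, int(100 * FS))))
        series = segment(rec, np.zeros(rec.n_samples, bool), edge_pad_s=1.0)
        assert series.n_segments == 1
        seg = series.segments[0]
        assert (seg.start_s, seg.end_s) == (1.0, 99.0)

    def test_short_runs_removed(self):
        # artifact splits signal into a 0.5 s and a 30 s clean run
        n = int(31 * FS)
        mask = np.zeros(n, bool)
        mask[int(0.5 * FS)] = True
        rec = _rec(np.random.default_rng(1).normal(size=(4, n)))
        series = segment(rec, mask, min_segment_s=1.0, edge_pad_s=0.0)
        assert series.n_segments == 1
        assert series.segments[0].duration_s > 29.0

    def test_alternating_pattern_fully_removed(self):
        # 2 s clean / 1-sample artifact; edge_pad 0.6 leaves runs < 1 s
        n = int(20 * FS)
        mask = np.zeros(n, bool)
        mask[:: int(2 * FS)] = True
        rec = _rec(np.random.default_rng(2).normal(size=(4, n)))
        series = segment(rec, mask, min_segment_s=1.0, edge_pad_s=0.6)
        assert series.n_segments == 0

    def test_no_flagged_sample_inside_segments_and_duration_bounded(self):
        rng = np.random.default_rng(3)
        n = int(200 * FS)
        rec = _rec(rng.normal(size=(4, n)))
        mask = rng.random(n) < 0.001
        series = segment(rec, mask, edge_pad_s=0.5)
        fs = FS
        for seg in series.segments:
            assert not mask[int(round(seg.start_s * fs)) : int(round(seg.end_s * fs))].any()
        assert series.total_clean_duration <= rec.duration_s


class TestZScore:
    def _series(self, rng, scale=1.0):
        blocks = [scale * rng.normal(size=(4, 500)), scale * rng.normal(size=(4, 800))]
        segs = [
            Segment(0.0, 500 / FS, blocks[0]),
            Segment(10.0, 10.0 + 800 / FS, blocks[1]),
        ]
        return SegmentSeries(segs, FS)

    def test_pooled_moments(self):
        series = zscore_segments(self._series(np.random.default_rng(4)))
        concat = series.concatenated()
        assert np.abs(concat.mean(axis=1)).max() < 1e-9
        np.testing.assert_allclose(concat.std(axis=1), 1.0, atol=1e-9)

    def test_idempotent_and_scale_invariant(self):
        rng = np.random.default_rng(5)
        base = self._series(rng)
        once = zscore_segments(base)
        twice = zscore_segments(once)
        for a, b in zip(once.segments, twice.segments):
            np.testing.assert_allclose(a.data, b.data, atol=1e-9)
        rng = np.random.default_rng(5)
        scaled = zscore_segments(self._series(rng, scale=5.0))
        for a, b in zip(once.segments, scaled.segments):
            np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_zero_variance_channel_rejected(self):
        segs = [Segment(0.0, 1.0, np.zeros((4, int(FS))))]
        with pytest.raises(DegenerateInputError):
            zscore_segments(SegmentSeries(segs, FS))


class TestInclusion:
    @pytest.mark.parametrize(
        "minutes,expected", [(19.9, False), (20.0, True), (25.0, True)]
    )
    def test_boundary(self, minutes, expected):
        n = int(minutes * 60 * FS)
        series = SegmentSeries(
            [Segment(0.0, n / FS, np.zeros((4, n)))], FS
        )
        assert passes_inclusion(series, min_total_s=1200.0) is expected

    def test_empty_series_excluded(self):
        assert passes_inclusion(SegmentSeries([], FS)) is False


def test_pipeline_rejects_nonfinite_input():
    x = np.ones((4, 100))
    x[2, 50] = np.nan
    with pytest.raises(InputError):
        EEGRecording(x, FS)


def test_pipeline_emits_only_unflagged_zscored_segments():
    spec = CohortSpec(n_patients=1, seed=0)
    rec, _ = simulate_eeg(0, "Propofol", spec, np.random.default_rng(9), duration_s=1500)
    cfg = PipelineConfig()
    series, mask = preprocess_recording(rec, cfg)
    fs = rec.sampling_rate
    for seg in series.segments:
        assert not mask[int(round(seg.start_s * fs)) : int(round(seg.end_s * fs))].any()
        assert seg.duration_s >= cfg.min_segment_s
    concat = series.concatenated()
    assert np.abs(concat.mean(axis=1)).max() < 1e-9
    np.testing.assert_allclose(concat.std(axis=1), 1.0, atol=1e-9)
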