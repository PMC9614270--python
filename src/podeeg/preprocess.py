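"""Raw EEG cleaning.

Turns a raw 4-channel frontal recording (Fp1, Fp2, F7, F8) into
artifact-free, z-scored time segments.  The stage order is fixed:

1. amplitude artifact mask from the patient's pooled 99 % amplitude
   quantile (computed on the raw signal, then dilated),
2. common average reference,
3. zero-phase 0.3-50 Hz Butterworth band-pass,
4. segmentation into maximal artifact-free runs, shrunk by an edge pad at
   every boundary and dropping runs shorter than 1 s,
5. per-patient z-scoring over the concatenated segments.

Patients with less than 20 min of clean EEG after this chain are excluded
from modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.signal import butter, sosfiltfilt

from .config import PipelineConfig
from .errors import ConfigError, ContractError, DegenerateInputError, InputError

FRONTAL_CHANNELS = ("Fp1", "Fp2", "F7", "F8")


@dataclass
class EEGRecording:
    """Multichannel EEG: (channels x samples) in microvolts."""

    signal: np.ndarray
    sampling_rate: float
    channel_labels: tuple = FRONTAL_CHANNELS
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise InputError("signal must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if not np.isfinite(self.signal).all():
            bad = np.argwhere(~np.isfinite(self.signal))
            raise InputError(
                f"non-finite samples in recording {self.patient_id!r}, "
                f"first at channel {bad[0][0]}, sample {bad[0][1]}"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Segment:
    start_s: float
    end_s: float
    data: np.ndarray  # channels x samples

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SegmentSeries:
    """Ordered, non-overlapping artifact-free segments of one patient.

    Intervals are half-open ``[start, end)`` in seconds from recording
    start.
    """

    segments: list
    sampling_rate: float
    source_id: str = ""

    @property
    def total_clean_duration(self) -> float:
        return float(sum(s.data.shape[1] for s in self.segments) / self.sampling_rate)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def blocks(self) -> list:
        return [s.data for s in self.segments]

    def concatenated(self) -> np.ndarray:
        if not self.segments:
            raise DegenerateInputError("empty segment series")
        return np.concatenate([s.data for s in self.segments], axis=1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def amplitude_artifact_mask(rec: EEGRecording, quantile: float = 0.99) -> np.ndarray:
    """Flag samples whose absolute amplitude on any channel exceeds the
    patient's pooled amplitude quantile.

    The quantile is computed over the pooled absolute amplitudes of all
    channels, giving one patient-level threshold; a sample is flagged when
    any channel exceeds it strictly.
    """
    if not 0.0 < quantile < 1.0:
        raise ConfigError(f"quantile must be in (0, 1), got {quantile}")
    if rec.n_samples == 0:
        raise ContractError("empty recording")
    absamp = np.abs(rec.signal)
    threshold = np.quantile(absamp, quantile)
    return (absamp > threshold).any(axis=0)


def dilate_mask(mask: np.ndarray, sampling_rate: float, width_s: float) -> np.ndarray:
    """Grow each flagged sample to the enclosing window of ``width_s``
    (spikes have ringing neighborhoods)."""
    if width_s <= 0:
        return mask.copy()
    w = max(1, int(round(width_s * sampling_rate)))
    return binary_dilation(mask, structure=np.ones(2 * (w // 2) + 1, dtype=bool))


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the across-channel mean from every sample."""
    if rec.n_channels < 2:
        raise ContractError("common average reference needs >= 2 channels")
    referenced = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return EEGRecording(referenced, rec.sampling_rate, rec.channel_labels, rec.patient_id)


def bandpass(
    rec: EEGRecording,
    low: float = 0.3,
    high: float = 50.0,
    order: int = 5,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    nyquist = rec.sampling_rate / 2.0
    if high >= nyquist:
        raise ConfigError(
            f"upper band edge {high} Hz must be below Nyquist ({nyquist} Hz)"
        )
    sos = butter(order, [low, high], btype="band", fs=rec.sampling_rate, output="sos")
    filtered = sosfiltfilt(sos, rec.signal, axis=1)
    return EEGRecording(filtered, rec.sampling_rate, rec.channel_labels, rec.patient_id)


def _clean_runs(mask: np.ndarray):
    """Maximal runs of unflagged samples as half-open (start, stop) pairs."""
    clean = ~np.asarray(mask, dtype=bool)
    if not clean.any():
        return []
    padded = np.concatenate(([False], clean, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def segment(
    rec: EEGRecording,
    artifact_mask: np.ndarray,
    min_segment_s: float = 1.0,
    edge_pad_s: float = 1.0,
) -> SegmentSeries:
    """Cut the recording into maximal artifact-free runs.

    Every run is shrunk by ``edge_pad_s`` at both boundaries (edges next to
    artifacts and the recording edges both carry filter edge effects), and
    runs shorter than ``min_segment_s`` after shrinking are dropped.  No
    flagged sample ever appears inside a returned segment.
    """
    if artifact_mask.shape != (rec.n_samples,):
        raise ContractError("artifact mask is not aligned with the recording")
    fs = rec.sampling_rate
    pad = int(round(edge_pad_s * fs))
    min_len = int(round(min_segment_s * fs))
    segments = []
    for a, b in _clean_runs(artifact_mask):
        a2, b2 = a + pad, b - pad
        if b2 - a2 >= max(min_len, 1):
            segments.append(Segment(a2 / fs, b2 / fs, rec.signal[:, a2:b2]))
    return SegmentSeries(segments, fs, rec.patient_id)


def zscore_segments(series: SegmentSeries) -> SegmentSeries:
    """Standardize each channel over the concatenation of all segments.

    The pooled per-channel mean and standard deviation are computed across
    every segment of the patient, so the output is scale and offset
    invariant while preserving relative amplitude between segments.
    """
    if not series.segments:
        raise ContractError("cannot z-score an empty segment series")
    concat = series.concatenated()
    mean = concat.mean(axis=1, keepdims=True)
    std = concat.std(axis=1, keepdims=True)
    if np.any(std <= 0):
        bad = int(np.argmin(std))
        raise DegenerateInputError(f"zero-variance channel {bad}")
    scaled = [
        Segment(s.start_s, s.end_s, (s.data - mean) / std) for s in series.segments
    ]
    return SegmentSeries(scaled, series.sampling_rate, series.source_id)


def passes_inclusion(series: SegmentSeries, min_total_s: float = 1200.0) -> bool:
    """Patient-level inclusion: at least ``min_total_s`` (default 20 min)
    of clean EEG left after preprocessing.  The boundary counts as
    included."""
    return series.total_clean_duration >= min_total_s


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def preprocess_recording(
    rec: EEGRecording, config: PipelineConfig | None = None
) -> tuple[SegmentSeries, np.ndarray]:
    """Run the full cleaning chain; returns the z-scored segment series
    and the (dilated) artifact mask."""
    cfg = config or PipelineConfig()
    mask = amplitude_artifact_mask(rec, cfg.amp_quantile)
    mask = dilate_mask(mask, rec.sampling_rate, cfg.mask_dilate_s)
    rec = common_average_reference(rec)
    rec = bandpass(rec, cfg.bp_low, cfg.bp_high, cfg.filter_order)
    series = segment(rec, mask, cfg.min_segment_s, cfg.edge_pad_s)
    if series.segments:
        series = zscore_segments(series)
    return series, mask
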