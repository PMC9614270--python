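"""Burst-suppression quantification.

Burst suppression is the anesthetic EEG pattern in which near-isoelectric
("suppression") periods alternate with high-amplitude bursts.  From the
cleaned, z-scored segments we estimate a per-sample suppression timeline
and two scalar signatures:

* BSR (burst suppression ratio): suppressed time divided by the total
  clean (artifact-reduced) recording time,
* LSP (longest suppression phase): duration of the longest contiguous
  suppressed run; runs never bridge artifact gaps, since unobserved time
  cannot be claimed suppressed.

Detection uses a channel-averaged sliding RMS envelope.  Because the
signal is z-scored, the envelope threshold is expressed in z-units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .config import PipelineConfig
from .errors import ConfigError, DegenerateInputError
from .preprocess import SegmentSeries


@dataclass
class BurstSuppressionProfile:
    """Per-sample suppression timeline over the clean segments, plus the
    scalar signatures derived from it."""

    timelines: list            # one float array in [0, 1] per segment
    sampling_rate: float
    analyzed_duration_s: float

    @property
    def n_suppressed(self) -> int:
        return int(sum((tl > 0.5).sum() for tl in self.timelines))

    @property
    def n_samples(self) -> int:
        return int(sum(tl.size for tl in self.timelines))

    @property
    def bsr(self) -> float:
        return burst_suppression_ratio(self)

    @property
    def lsp_s(self) -> float:
        return longest_suppression_phase(self)


def _envelope(block: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Channel-averaged sliding RMS amplitude envelope."""
    w = max(1, int(round(window_s * fs)))
    power = uniform_filter1d(block**2, size=w, axis=-1, mode="nearest")
    return np.sqrt(power).mean(axis=0)


def _enforce_min_duration(flags: np.ndarray, min_samples: int) -> np.ndarray:
    """Keep only suppressed runs of at least ``min_samples``."""
    if min_samples <= 1:
        return flags
    out = np.zeros_like(flags)
    padded = np.concatenate(([False], flags, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    for a, b in zip(starts, stops):
        if b - a >= min_samples:
            out[a:b] = True
    return out


def suppression_timeline(
    series: SegmentSeries,
    threshold: float = 0.2,
    min_suppr_dur_s: float = 0.5,
    env_window_s: float = 0.25,
) -> BurstSuppressionProfile:
    """Estimate the suppression timeline of a z-scored segment series.

    A sample counts as suppressed when the smoothed amplitude envelope
    stays below ``threshold`` (z-units) for at least ``min_suppr_dur_s``.
    The suppressed set is monotone in the threshold: raising it never
    shrinks the set.
    """
    fs = series.sampling_rate
    min_samples = int(round(min_suppr_dur_s * fs))
    if min_samples < 1:
        raise ConfigError("min_suppr_dur_s is below one sample period")
    timelines = []
    for seg in series.segments:
        env = _envelope(seg.data, fs, env_window_s)
        flags = _enforce_min_duration(env < threshold, min_samples)
        timelines.append(flags.astype(float))
    return BurstSuppressionProfile(timelines, fs, series.total_clean_duration)


def burst_suppression_ratio(profile: BurstSuppressionProfile) -> float:
    """Suppressed time divided by the artifact-reduced recording time."""
    if profile.n_samples == 0:
        raise DegenerateInputError("empty burst-suppression profile")
    return profile.n_suppressed / profile.n_samples


def longest_suppression_phase(profile: BurstSuppressionProfile) -> float:
    """Duration (s) of the longest contiguous suppressed run.

    Runs are evaluated within each segment only, so suppression never
    spans an artifact gap; returns 0 when nothing is suppressed.
    """
    longest = 0
    for tl in profile.timelines:
        flags = tl > 0.5
        padded = np.concatenate(([False], flags, [False]))
        diff = np.diff(padded.astype(np.int8))
        runs = np.flatnonzero(diff == -1) - np.flatnonzero(diff == 1)
        if runs.size:
            longest = max(longest, int(runs.max()))
    return longest / profile.sampling_rate


def burst_profile(series: SegmentSeries, config: PipelineConfig | None = None) -> BurstSuppressionProfile:
    cfg = config or PipelineConfig()
    return suppression_timeline(
        series, cfg.bs_threshold_z, cfg.bs_min_dur_s, cfg.bs_env_window_s
    )
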