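"""Per-patient feature extraction.

Runs the cleaning chain and derives the three feature streams used by the
classifiers:

* scalar burst-suppression signatures (BSR, LSP),
* spectral frames: per-2-min-frame Welch log-power vectors,
* covariance frames: per-frame 25x25 SPD matrices from the multi-band
  stack (6 bands x 4 channels + the suppression timeline), estimated per
  segment with exact OAS shrinkage and averaged arithmetically within each
  frame.

Covariance frames flagged by the adaptive Riemannian potato are removed
from the covariance *and* the spectral stream, so both classifiers see the
same retained frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burst import burst_profile
from .config import PipelineConfig
from .errors import DegenerateInputError
from .preprocess import EEGRecording, passes_inclusion, preprocess_recording
from .riemann import multiband_stack, oas_covariance, riemannian_potato
from .simulate import CohortSpec, SyntheticPatient, clinical_table, iter_cohort
from .spectral import compute_spectral_frames, frame_assignment, frame_average


@dataclass
class PatientFeatures:
    """Everything modelling needs for one included patient."""

    patient_id: str
    bsr: float
    lsp_s: float
    spec_frames: np.ndarray      # n_frames x n_freqs, log10 PSD
    cov_frames: np.ndarray       # n_frames x 25 x 25, SPD
    frame_index: np.ndarray      # clean-time frame numbers (shared streams)
    clean_duration_s: float

    @property
    def n_frames(self) -> int:
        return self.spec_frames.shape[0]


@dataclass
class CohortFeatures:
    """Feature container for a cohort: one PatientFeatures per included
    patient plus the clinical table (with POD labels when available)."""

    features: dict                # patient_id -> PatientFeatures
    clinical: pd.DataFrame        # indexed by patient_id
    excluded: list = field(default_factory=list)
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @property
    def patient_ids(self) -> list:
        return list(self.features)

    @property
    def labels(self) -> pd.Series:
        return self.clinical.loc[self.patient_ids, "pod_label"]

    def subset(self, ids) -> "CohortFeatures":
        ids = list(ids)
        return CohortFeatures(
            {i: self.features[i] for i in ids},
            self.clinical.loc[ids],
            config=self.config,
        )


def extract_patient_features(
    rec: EEGRecording, config: PipelineConfig | None = None
) -> PatientFeatures | None:
    """Full feature extraction for one recording.

    Returns ``None`` when the patient fails the clean-duration inclusion
    rule (< 20 min of artifact-free EEG).
    """
    cfg = config or PipelineConfig()
    series, _ = preprocess_recording(rec, cfg)
    if not series.segments or not passes_inclusion(series, cfg.min_total_min * 60.0):
        return None

    profile = burst_profile(series, cfg)
    spec_series = compute_spectral_frames(series, cfg)

    blocks = multiband_stack(
        series.blocks(), profile.timelines, series.sampling_rate,
        cfg.bands, cfg.filter_order,
    )
    seg_covs = np.stack([oas_covariance(b.data) for b in blocks])
    idx = frame_assignment(series, cfg.frame_len_s)
    frame_ids, cov_frames = frame_average(seg_covs, idx)
    if not np.array_equal(frame_ids, spec_series.frame_starts_s / cfg.frame_len_s):
        raise AssertionError("spectral and covariance frame bins diverged")

    if len(cov_frames) >= 2:
        try:
            keep = riemannian_potato(
                list(cov_frames), cfg.potato_z, cfg.potato_adapt, cfg.potato_burn_in
            )
        except DegenerateInputError:
            keep = np.ones(len(cov_frames), dtype=bool)
    else:
        keep = np.ones(len(cov_frames), dtype=bool)

    return PatientFeatures(
        patient_id=rec.patient_id,
        bsr=profile.bsr,
        lsp_s=profile.lsp_s,
        spec_frames=spec_series.log_frames()[keep],
        cov_frames=cov_frames[keep],
        frame_index=frame_ids[keep],
        clean_duration_s=series.total_clean_duration,
    )


def extract_cohort_features(
    patients, config: PipelineConfig | None = None
) -> CohortFeatures:
    """Extract features for an iterable of :class:`SyntheticPatient` (or
    ``(recording, clinical)`` pairs), applying the exclusion rules.

    Accepts a generator so large cohorts can stream patient by patient
    without holding every raw signal in memory.
    """
    cfg = config or PipelineConfig()
    feats: dict = {}
    records = []
    excluded = []
    for p in patients:
        if isinstance(p, SyntheticPatient):
            rec, clin = p.recording, p.clinical
        else:
            rec, clin = p
        pf = extract_patient_features(rec, cfg)
        if pf is None:
            excluded.append(clin.patient_id)
            continue
        pf.patient_id = pf.patient_id or clin.patient_id
        feats[clin.patient_id] = pf
        records.append(clin)
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} patients with <{cfg.min_total_min:g} min clean EEG"
        )
    return CohortFeatures(feats, clinical_table(records), excluded, cfg)


def extract_from_spec(spec: CohortSpec, config: PipelineConfig | None = None) -> CohortFeatures:
    """Simulate a cohort and extract its features in one streaming pass."""
    return extract_cohort_features(iter_cohort(spec), config)
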