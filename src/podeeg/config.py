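"""Pipeline configuration.

One flat dataclass holds every tunable of the processing and modelling
chain, with the defaults used throughout the package.  Configs load from
TOML (stdlib ``tomllib``); unknown keys are rejected so that typos fail
loudly, and the full config is echoed into every model bundle.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field

from .errors import ConfigError

#: Frequency bands of the multi-band stack (Hz): delta, theta, lower alpha,
#: higher alpha, lower beta, higher beta.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.3, 4.0),
    (4.0, 8.0),
    (8.0, 12.0),
    (12.0, 15.0),
    (15.0, 20.0),
    (20.0, 30.0),
)


@dataclass
class PipelineConfig:
    # --- artifact mask ---
    amp_quantile: float = 0.99        # per-patient amplitude quantile, pooled over channels
    mask_dilate_s: float = 0.1        # dilation window around flagged samples (s)
    # --- filtering ---
    bp_low: float = 0.3               # band-pass edges (Hz)
    bp_high: float = 50.0
    filter_order: int = 5             # Butterworth order, applied zero-phase
    # --- segmentation ---
    edge_pad_s: float = 1.0           # shrink at every segment boundary (s)
    min_segment_s: float = 1.0        # segments shorter than this are dropped
    min_total_min: float = 20.0       # patient inclusion: clean EEG required (min)
    # --- burst suppression ---
    bs_env_window_s: float = 0.25     # RMS envelope window (s)
    bs_threshold_z: float = 0.2       # envelope threshold in z-units
    bs_min_dur_s: float = 0.5         # minimum suppression duration (s)
    # --- spectra ---
    welch_window_s: float = 1.0       # Hann window length (s), 50 % overlap
    welch_overlap: float = 0.5
    psd_fmin: float = 0.5             # fixed output grid (Hz)
    psd_fmax: float = 50.0
    psd_df: float = 0.5
    # --- frames ---
    frame_len_s: float = 120.0        # clean-time frame length (s)
    # --- multi-band covariance ---
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    # --- Riemannian potato ---
    potato_z: float = 2.5
    potato_adapt: float = 0.1
    potato_burn_in: int = 10
    # --- SPD numerics ---
    karcher_tol: float = 1e-9
    karcher_max_iter: int = 100
    eig_floor: float = 1e-12
    # --- bagged SVM ensemble ---
    n_estimators: int = 25            # R saved estimators
    auc_threshold: float = 0.70       # initial acceptance threshold
    iter_per_level: int = 5           # failures before the threshold decays
    threshold_decay: float = 0.025    # multiplicative decay per level
    n_frames_major: int = 10          # frames sampled per majority patient
    n_frames_minor_cov: int = 20      # frames per minority patient (covariance)
    svm_c: float = 1.0
    # --- balanced random forest ---
    n_trees: int = 500
    # --- fusion ---
    auc_floor: float = 0.55           # training AUC needed to enter p_m
    pm_cutoff: float = 0.25           # low-probability override threshold
    # --- evaluation ---
    min_group_size: int = 20          # smaller agent groups fold into "all"
    n_repeats: int = 10
    n_folds: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.amp_quantile < 1.0:
            raise ConfigError(f"amp_quantile must be in (0, 1), got {self.amp_quantile}")
        if self.bp_low <= 0 or self.bp_high <= self.bp_low:
            raise ConfigError("band-pass edges must satisfy 0 < low < high")
        if not 0 < self.welch_overlap < 1:
            raise ConfigError("welch_overlap must be in (0, 1)")
        if self.frame_len_s <= 0:
            raise ConfigError("frame_len_s must be positive")
        if self.n_estimators < 1:
            raise ConfigError("n_estimators must be >= 1")
        self.bands = tuple(tuple(b) for b in self.bands)

    # -- serialization --------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
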