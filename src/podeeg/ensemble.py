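"""Two-level undersampled bagging of weighted SVMs for frame features.

Patients differ both in class (POD is the minority) and in how many
2-minute frames they contribute, so training resamples at two levels per
candidate estimator:

1. patient level: keep every minority patient, undersample the majority
   to at least one third of its size (never below the minority count),
2. frame level: sample a fixed number of frames per patient (for the
   covariance stream, more frames per minority patient).

Each candidate is a class-weighted linear SVM fit on the sampled frames;
it is saved only if its AUC over *all* frames of the full training set
reaches an acceptance threshold.  After 5 consecutive rejections the
threshold decays by 2.5 % — so training terminates with exactly R saved
estimators.  A patient's predicted POD probability is the mean ratio of
frames classified POD across the R estimators:

    p = (1 / (R * T_P)) * sum_r sum_t c_{r,t}

For the covariance stream, frames are SPD matrices: a class-balanced
Riemannian reference point is computed from one initial sampling draw and
every frame is projected to its tangent space before classification; the
reference is stored with the ensemble so new cohorts are projected without
refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .config import PipelineConfig
from .errors import ContractError, DegenerateInputError, NumericalError
from .riemann import balanced_reference, tangent_project


@dataclass
class FrameDataset:
    """Per-patient frame features plus patient-level labels.

    ``frames[pid]`` is (T_i x d) for kind="spec" (log-power vectors) or
    (T_i x p x p) for kind="cov" (SPD matrices).
    """

    frames: dict
    labels: dict               # pid -> 0/1
    kind: str                  # "spec" | "cov"

    def __post_init__(self) -> None:
        if self.kind not in ("spec", "cov"):
            raise ContractError(f"unknown feature kind {self.kind!r}")
        if set(self.frames) != set(self.labels):
            raise ContractError("frames and labels cover different patients")

    @property
    def patient_ids(self) -> list:
        return list(self.frames)

    def class_ids(self, label: int) -> list:
        return [p for p in self.frames if self.labels[p] == label]


@dataclass
class BaggedEnsemble:
    estimators: list                      # (scaler, svm) pairs
    kind: str
    reference: np.ndarray | None = None   # SPD reference point (cov only)
    threshold_history: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    training_patient_ids: list = field(default_factory=list)

    @property
    def n_estimators(self) -> int:
        return len(self.estimators)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_patients(dataset: FrameDataset, rng: np.random.Generator) -> list:
    """Undersample the majority class on the patient level.

    All minority patients are kept; the majority is subsampled to
    ``max(n_minority, ceil(n_majority / 3))``.
    """
    pos, neg = dataset.class_ids(1), dataset.class_ids(0)
    if not pos or not neg:
        raise ContractError("both classes must be present")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    n_keep = max(len(minority), math.ceil(len(majority) / 3))
    kept = list(rng.choice(majority, size=min(n_keep, len(majority)), replace=False))
    return sorted(minority + kept)


def sample_frames(
    dataset: FrameDataset,
    patient_ids,
    n_major: int,
    n_minor: int,
    rng: np.random.Generator,
):
    """Sample up to a fixed number of frames per patient.

    Minority-class patients contribute up to ``n_minor`` frames, majority
    up to ``n_major`` (equal for the spectral stream); patients with fewer
    frames contribute all of them.  Returns (frame array, frame labels,
    frame patient ids).
    """
    if n_minor < n_major and dataset.kind == "cov":
        raise ContractError("covariance sampling requires n_minor >= n_major")
    pos = dataset.class_ids(1)
    neg = dataset.class_ids(0)
    minority_label = 1 if len(pos) <= len(neg) else 0
    rows, labels, owners = [], [], []
    for pid in patient_ids:
        frames = dataset.frames[pid]
        cap = n_minor if dataset.labels[pid] == minority_label else n_major
        if len(frames) > cap:
            idx = rng.choice(len(frames), size=cap, replace=False)
            frames = frames[np.sort(idx)]
        rows.append(np.asarray(frames))
        labels.extend([dataset.labels[pid]] * len(frames))
        owners.extend([pid] * len(frames))
    return np.concatenate(rows), np.asarray(labels), owners


def _flatten(dataset_vectors: dict, labels: dict):
    xs, ys = [], []
    for pid, v in dataset_vectors.items():
        xs.append(v)
        ys.extend([labels[pid]] * len(v))
    return np.concatenate(xs), np.asarray(ys)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _project_dataset(dataset: FrameDataset, cfg: PipelineConfig, rng) -> tuple:
    """Covariance stream: fix the tangent space from one balanced draw."""
    ids = sample_patients(dataset, rng)
    mats, frame_labels, _ = sample_frames(
        dataset, ids, cfg.n_frames_major, cfg.n_frames_minor_cov, rng
    )
    reference = balanced_reference(
        list(mats), frame_labels, tol=cfg.karcher_tol, max_iter=cfg.karcher_max_iter
    )
    vectors = {
        pid: tangent_project(np.asarray(dataset.frames[pid]), reference)
        for pid in dataset.patient_ids
    }
    return reference, vectors


def train_bagging(
    dataset: FrameDataset,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | int = 0,
    max_total_iter: int = 20000,
) -> BaggedEnsemble:
    """Train the bagged ensemble with the adaptive acceptance threshold."""
    cfg = config or PipelineConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not dataset.frames:
        raise ContractError("empty dataset")

    reference = None
    if dataset.kind == "cov":
        reference, vectors = _project_dataset(dataset, cfg, rng)
        dataset = FrameDataset(vectors, dataset.labels, "cov")
    full_x, full_y = _flatten(dataset.frames, dataset.labels)

    n_minor = cfg.n_frames_minor_cov if dataset.kind == "cov" else cfg.n_frames_major
    threshold = cfg.auc_threshold
    estimators, history = [], []
    failures = 0
    for it in range(max_total_iter):
        ids = sample_patients(dataset, rng)
        x, y, _ = sample_frames(dataset, ids, cfg.n_frames_major, n_minor, rng)
        scaler = StandardScaler().fit(x)
        svm = LinearSVC(
            C=cfg.svm_c,
            class_weight="balanced",
            dual=False,
            tol=1e-3,   # soft-margin on noisy frames; tighter tolerances
            random_state=int(rng.integers(2**31 - 1)),   # cost 5x for no AUC gain
        )
        svm.fit(scaler.transform(x), y)
        scores = _linear_scores(scaler, svm, full_x)
        auc = roc_auc_score(full_y, scores)
        saved = auc >= threshold
        history.append(
            {"iteration": it, "threshold": threshold, "auc": float(auc), "saved": bool(saved)}
        )
        if saved:
            estimators.append((scaler, svm))
            failures = 0
            if len(estimators) >= cfg.n_estimators:
                break
        else:
            failures += 1
            if failures == cfg.iter_per_level:
                threshold *= 1.0 - cfg.threshold_decay
                failures = 0
    else:
        raise NumericalError(
            f"bagging did not save {cfg.n_estimators} estimators "
            f"in {max_total_iter} iterations"
        )
    return BaggedEnsemble(
        estimators=estimators,
        kind=dataset.kind,
        reference=reference,
        threshold_history=history,
        config={
            "n_estimators": cfg.n_estimators,
            "auc_threshold": cfg.auc_threshold,
            "iter_per_level": cfg.iter_per_level,
            "threshold_decay": cfg.threshold_decay,
            "n_frames_major": cfg.n_frames_major,
            "n_frames_minor": n_minor,
        },
        training_patient_ids=sorted(dataset.patient_ids),
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _linear_scores(scaler: StandardScaler, svm: LinearSVC, x: np.ndarray) -> np.ndarray:
    """Decision values of scaler+linear-SVM computed in one matrix product
    (identical to ``svm.decision_function(scaler.transform(x))`` without
    the per-call validation overhead)."""
    coef = svm.coef_.ravel()
    if x.shape[-1] != coef.shape[0]:
        raise ContractError(
            f"feature dimension {x.shape[-1]} does not match the "
            f"ensemble's training dimension {coef.shape[0]}"
        )
    w = coef / scaler.scale_
    b = float(svm.intercept_[0]) - float((scaler.mean_ / scaler.scale_) @ coef)
    return x @ w + b


def predict_patient(ensemble: BaggedEnsemble, frames: np.ndarray) -> float:
    """Mean ratio of frames classified POD over estimators and frames.

    ``frames`` are the patient's raw frame features (SPD matrices for the
    covariance stream; they are projected to the ensemble's stored tangent
    space).  No labels are needed, so a frozen ensemble applies unchanged
    to a new cohort.
    """
    frames = np.asarray(frames)
    if frames.shape[0] == 0:
        raise DegenerateInputError("patient has no frames")
    if ensemble.kind == "cov":
        if ensemble.reference is None:
            raise ContractError("covariance ensemble is missing its reference point")
        if frames.ndim == 3:
            frames = tangent_project(frames, ensemble.reference)
    total = 0.0
    for scaler, svm in ensemble.estimators:
        decision = _linear_scores(scaler, svm, frames)
        total += float((decision > 0).mean())   # decision exactly 0 -> non-POD
    return total / ensemble.n_estimators


def predict_dataset(ensemble: BaggedEnsemble, frames_by_patient: dict) -> dict:
    """Batched :func:`predict_patient` over a cohort (one projection and
    one matrix product per estimator for all patients together)."""
    ids = list(frames_by_patient)
    if not ids:
        return {}
    counts = [len(frames_by_patient[p]) for p in ids]
    if min(counts) == 0:
        raise DegenerateInputError("a patient has no frames")
    stacked = np.concatenate([np.asarray(frames_by_patient[p]) for p in ids])
    if ensemble.kind == "cov" and stacked.ndim == 3:
        if ensemble.reference is None:
            raise ContractError("covariance ensemble is missing its reference point")
        stacked = tangent_project(stacked, ensemble.reference)
    pod_ratio = np.zeros(stacked.shape[0])
    for scaler, svm in ensemble.estimators:
        pod_ratio += _linear_scores(scaler, svm, stacked) > 0
    pod_ratio /= ensemble.n_estimators
    bounds = np.cumsum([0] + counts)
    return {
        pid: float(pod_ratio[a:b].mean())
        for pid, a, b in zip(ids, bounds[:-1], bounds[1:])
    }
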