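"""Evaluation protocol.

Repeated, patient-grouped, label-stratified cross-validation of the full
classifier stack; medication-group stratified training with an
all-medications fallback; and transfer evaluation of a frozen model set
on a second cohort (nothing refit — the robustness check).

Every training-fold statistic (covariance reference point, g-mean
thresholds, shifts, forests, ensembles) is fit on the training folds
only; ``run_cv`` records the patient ids and an input hash per fold so
leakage is auditable.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .errors import ContractError
from .features import CohortFeatures
from .fusion import npv
from .model import DeliriumRiskModel, DeliriumRiskResults

EEG_GROUPS = ("Propofol", "Desflurane", "Sevoflurane")
PROB_COLS = {
    "patient": "p_patient",
    "patient_burst": "p_patient_burst",
    "spec": "p_spec",
    "cov": "p_cov",
    "comb": "p_comb",
}


def roc_auc(probs, labels) -> float:
    """AUC-ROC (Mann-Whitney normalization, ties counted half); NaN when
    only one class is present."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, np.asarray(probs, dtype=float)))


@dataclass
class CVPlan:
    n_repeats: int = 10
    n_folds: int = 10
    seed: int = 0


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    train_ids: list
    test_ids: list
    train_hash: str
    metrics: dict
    fit_train_ids: list    # ids the fitted stack reports using


def _hash_ids(ids, labels) -> str:
    h = hashlib.sha256()
    for i, l in zip(ids, labels):
        h.update(f"{i}:{l};".encode())
    return h.hexdigest()


def run_cv(
    features: CohortFeatures,
    config: PipelineConfig | None = None,
    plan: CVPlan | None = None,
) -> tuple[pd.DataFrame, list]:
    """Repeated stratified CV of the full stack on one cohort.

    Folds are per patient (all frames of a patient stay together) and
    stratified by POD label.  Returns a per-fold metric table (AUC per
    classifier plus NPV) and the fold records for auditing.
    """
    cfg = config or features.config or PipelineConfig()
    plan = plan or CVPlan(cfg.n_repeats, cfg.n_folds)
    ids = np.asarray(features.patient_ids)
    labels = features.labels.to_numpy(dtype=int)
    rows, records = [], []
    for rep in range(plan.n_repeats):
        splitter = StratifiedKFold(
            n_splits=plan.n_folds, shuffle=True, random_state=plan.seed * 1000 + rep
        )
        for fold, (tr, te) in enumerate(splitter.split(ids, labels)):
            if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
                warnings.warn(f"repeat {rep} fold {fold} lacks a class; skipped")
                continue
            train_feats = features.subset(ids[tr])
            test_feats = features.subset(ids[te])
            res = DeliriumRiskModel(train_feats, cfg).fit(
                seed=plan.seed * 100003 + rep * 101 + fold
            )
            metrics = res.evaluate(test_feats)
            rows.append({"repeat": rep, "fold": fold, **metrics})
            records.append(
                FoldRecord(
                    repeat=rep,
                    fold=fold,
                    train_ids=sorted(ids[tr]),
                    test_ids=sorted(ids[te]),
                    train_hash=_hash_ids(sorted(ids[tr]), labels[tr][np.argsort(ids[tr])]),
                    metrics=metrics,
                    fit_train_ids=sorted(res.training_patient_ids),
                )
            )
    return pd.DataFrame(rows), records


# ---------------------------------------------------------------------------
# medication-group models
# ---------------------------------------------------------------------------

@dataclass
class GroupedModelSet:
    """One fitted stack per maintenance-agent group plus an
    all-medications fallback; every patient routes to exactly one."""

    groups: dict               # group name -> DeliriumRiskResults
    all_model: DeliriumRiskResults
    min_group_size: int = 20

    def route(self, agent: str) -> str:
        return agent if agent in self.groups else "all"

    def model_for(self, agent: str) -> DeliriumRiskResults:
        return self.groups.get(agent, self.all_model)


def route_and_train_groups(
    features: CohortFeatures,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> GroupedModelSet:
    """Train one stack per sufficiently large agent group, plus the
    all-medications stack used for every other patient."""
    cfg = config or features.config or PipelineConfig()
    agents = features.clinical.loc[features.patient_ids, "maintenance_agent"]
    all_results = DeliriumRiskModel(features, cfg).fit(seed=seed)
    groups = {}
    for gi, group in enumerate(EEG_GROUPS):
        members = list(agents.index[agents == group])
        group_labels = features.labels.loc[members]
        if len(members) < cfg.min_group_size or group_labels.nunique() < 2:
            if members:
                warnings.warn(
                    f"group {group} too small or single-class; folded into all-medications"
                )
            continue
        groups[group] = DeliriumRiskModel(features.subset(members), cfg).fit(
            seed=seed + 17 * (gi + 1)
        )
    return GroupedModelSet(groups, all_results, cfg.min_group_size)


def predict_grouped(model_set: GroupedModelSet, features: CohortFeatures) -> pd.DataFrame:
    """Apply the frozen grouped models to a cohort; each patient is
    scored by the model of their maintenance-agent group (or the
    all-medications model)."""
    agents = features.clinical.loc[features.patient_ids, "maintenance_agent"]
    parts = []
    for group in list(model_set.groups) + ["all"]:
        if group == "all":
            members = [p for p in features.patient_ids
                       if model_set.route(agents.loc[p]) == "all"]
            model = model_set.all_model
        else:
            members = [p for p in features.patient_ids if agents.loc[p] == group]
            model = model_set.groups[group]
        if not members:
            continue
        rep = model.predict(features.subset(members))
        rep["group"] = group
        parts.append(rep)
    report = pd.concat(parts).loc[features.patient_ids]
    return report


def transfer_evaluate(
    model_set: GroupedModelSet, features: CohortFeatures
) -> tuple[pd.DataFrame, dict]:
    """Evaluate a frozen grouped model set on a new cohort.

    No parameter of any stage is refit: covariance frames are projected
    to each saved reference point and the saved probability shifts are
    applied.  Returns the risk report and AUC/NPV metrics overall and per
    group.
    """
    report = predict_grouped(model_set, features)
    if "pod_label" not in report.columns:
        raise ContractError("transfer evaluation requires POD labels")
    y = report["pod_label"].to_numpy(dtype=int)
    metrics = {f"auc_{k}": roc_auc(report[col], y) for k, col in PROB_COLS.items()}
    metrics["npv_comb"] = npv(report["p_comb"], y)
    for group, sub in report.groupby("group"):
        metrics[f"auc_comb[{group}]"] = roc_auc(
            sub["p_comb"], sub["pod_label"].to_numpy(dtype=int)
        )
    return report, metrics


def mean_roc_curve(probs_list, labels_list, fpr_grid=None):
    """Vertically averaged ROC curve over folds at a fixed FPR grid."""
    from sklearn.metrics import roc_curve

    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    for p, y in zip(probs_list, labels_list):
        fpr, tpr, _ = roc_curve(y, p)
        tprs.append(np.interp(fpr_grid, fpr, tpr))
    return fpr_grid, np.mean(tprs, axis=0)
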