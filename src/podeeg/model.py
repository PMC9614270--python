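"""Model/Results surface for the combined POD risk evaluation.

:class:`DeliriumRiskModel` is built from extracted cohort features (or
directly from a synthetic cohort spec); :meth:`DeliriumRiskModel.fit`
trains the full classifier stack —

* ``patient``: balanced random forest on clinical features alone,
* ``patient_burst``: the same forest plus BSR / LSP,
* ``spec`` / ``cov``: bagged weighted-SVM ensembles on spectral and
  tangent-projected covariance frames,
* the fusion state (g-mean threshold shifts and the max/min combination)

— and returns a :class:`DeliriumRiskResults` carrying the fitted
classifiers, their training diagnostics, and ``predict`` / ``summary``.
A fitted results object applies unchanged to a new cohort: nothing is
refit at prediction time (the covariance reference point and the
probability shifts are frozen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .ensemble import BaggedEnsemble, FrameDataset, predict_dataset, train_bagging
from .errors import ContractError
from .features import CohortFeatures, extract_cohort_features, extract_from_spec
from .forest import BalancedRandomForest, predict_rf, train_balanced_rf
from .fusion import FusionState, apply_fusion, npv, select_shifts


def clinical_with_burst(features: CohortFeatures) -> pd.DataFrame:
    """Clinical table of the included patients with BSR / LSP appended."""
    table = features.clinical.loc[features.patient_ids].copy()
    table["bsr"] = [features.features[p].bsr for p in features.patient_ids]
    table["lsp_s"] = [features.features[p].lsp_s for p in features.patient_ids]
    return table


class DeliriumRiskModel:
    """POD risk model for one cohort (optionally one medication group)."""

    def __init__(self, features: CohortFeatures, config: PipelineConfig | None = None):
        if not features.features:
            raise ContractError("no included patients in the cohort features")
        self.features = features
        self.config = config or features.config or PipelineConfig()

    @classmethod
    def from_cohort(cls, patients, config: PipelineConfig | None = None) -> "DeliriumRiskModel":
        return cls(extract_cohort_features(patients, config), config)

    @classmethod
    def from_spec(cls, spec, config: PipelineConfig | None = None) -> "DeliriumRiskModel":
        return cls(extract_from_spec(spec, config), config)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "DeliriumRiskResults":
        from sklearn.metrics import roc_auc_score

        cfg = self.config
        feats = self.features
        ids = feats.patient_ids
        labels = feats.labels.to_numpy(dtype=int)
        if len(np.unique(labels)) != 2:
            raise ContractError("training cohort must contain both classes")
        label_map = dict(zip(ids, labels))
        rng = np.random.default_rng(seed)
        sub = rng.integers(2**31 - 1, size=4)

        table = clinical_with_burst(feats)
        rf_patient = train_balanced_rf(
            table, labels, with_burst=False, n_trees=cfg.n_trees, random_state=int(sub[0])
        )
        rf_burst = train_balanced_rf(
            table, labels, with_burst=True, n_trees=cfg.n_trees, random_state=int(sub[1])
        )

        spec_ds = FrameDataset(
            {p: feats.features[p].spec_frames for p in ids}, label_map, "spec"
        )
        cov_ds = FrameDataset(
            {p: feats.features[p].cov_frames for p in ids}, label_map, "cov"
        )
        ens_spec = train_bagging(spec_ds, cfg, np.random.default_rng(int(sub[2])))
        ens_cov = train_bagging(cov_ds, cfg, np.random.default_rng(int(sub[3])))

        # training-set probabilities for threshold / shift selection:
        # out-of-bag for the forests (in-sample balanced-RF probabilities
        # are near-degenerate), in-sample frame ratios for the ensembles
        x_burst = predict_rf(rf_burst, table)
        oob_burst = rf_burst.oob_proba(_encode_for(rf_burst, table))
        p_burst_train = np.where(np.isnan(oob_burst), x_burst, oob_burst)
        oob_pat = rf_patient.oob_proba(_encode_for(rf_patient, table))
        p_pat_train = np.where(np.isnan(oob_pat), predict_rf(rf_patient, table), oob_pat)
        spec_pred = predict_dataset(ens_spec, {p: feats.features[p].spec_frames for p in ids})
        cov_pred = predict_dataset(ens_cov, {p: feats.features[p].cov_frames for p in ids})
        p_spec_train = np.array([spec_pred[p] for p in ids])
        p_cov_train = np.array([cov_pred[p] for p in ids])

        fusion = select_shifts(
            p_burst_train, p_spec_train, p_cov_train, labels,
            auc_floor=cfg.auc_floor, pm_cutoff=cfg.pm_cutoff,
        )
        training_auc = dict(fusion.training_auc)
        training_auc["patient"] = float(roc_auc_score(labels, p_pat_train))

        return DeliriumRiskResults(
            model=self,
            rf_patient=rf_patient,
            rf_burst=rf_burst,
            ens_spec=ens_spec,
            ens_cov=ens_cov,
            fusion=fusion,
            training_auc=training_auc,
            training_patient_ids=list(ids),
            seed=seed,
            config=cfg,
        )


def _encode_for(forest: BalancedRandomForest, table: pd.DataFrame) -> np.ndarray:
    from .forest import BURST_COLS, encode_clinical

    with_burst = BURST_COLS[0] in forest.feature_names
    x, _ = encode_clinical(table, with_burst=with_burst)
    return x


@dataclass
class DeliriumRiskResults:
    """Fitted classifier stack with frozen fusion state."""

    model: DeliriumRiskModel
    rf_patient: BalancedRandomForest
    rf_burst: BalancedRandomForest
    ens_spec: BaggedEnsemble
    ens_cov: BaggedEnsemble
    fusion: FusionState
    training_auc: dict
    training_patient_ids: list
    seed: int
    config: PipelineConfig

    # ------------------------------------------------------------------
    def predict(self, features: CohortFeatures | None = None) -> pd.DataFrame:
        """Per-patient risk report.

        Columns: raw probabilities of each classifier, the shifted
        variants, the combined risk ``p_comb`` and the binary call at the
        fixed 0.5 threshold.  No stage is refit: covariance frames of a
        new cohort are projected to the saved reference point and the
        saved shifts are applied.
        """
        feats = features if features is not None else self.model.features
        ids = feats.patient_ids
        table = clinical_with_burst(feats)
        p_pat = predict_rf(self.rf_patient, table)
        p_burst = predict_rf(self.rf_burst, table)
        spec_pred = predict_dataset(self.ens_spec, {p: feats.features[p].spec_frames for p in ids})
        cov_pred = predict_dataset(self.ens_cov, {p: feats.features[p].cov_frames for p in ids})
        p_spec = np.array([spec_pred[p] for p in ids])
        p_cov = np.array([cov_pred[p] for p in ids])
        p_comb, shifted = apply_fusion(self.fusion, p_burst, p_spec, p_cov)
        report = pd.DataFrame(
            {
                "p_patient": p_pat,
                "p_patient_burst": p_burst,
                "p_spec": p_spec,
                "p_cov": p_cov,
                "p_patient_burst_shifted": shifted["patient_burst"],
                "p_spec_shifted": shifted["spec"],
                "p_cov_shifted": shifted["cov"],
                "p_comb": np.atleast_1d(p_comb),
                "call": np.atleast_1d(p_comb) >= 0.5,
            },
            index=pd.Index(ids, name="patient_id"),
        )
        if "pod_label" in feats.clinical.columns:
            report["pod_label"] = feats.clinical.loc[ids, "pod_label"].to_numpy()
        return report

    def evaluate(self, features: CohortFeatures | None = None) -> dict:
        """AUC per classifier and NPV of the combined call on a labelled
        cohort (the training cohort by default)."""
        from sklearn.metrics import roc_auc_score

        report = self.predict(features)
        if "pod_label" not in report.columns:
            raise ContractError("evaluation requires POD labels")
        y = report["pod_label"].to_numpy(dtype=int)
        out = {}
        for name, col in [
            ("patient", "p_patient"),
            ("patient_burst", "p_patient_burst"),
            ("spec", "p_spec"),
            ("cov", "p_cov"),
            ("comb", "p_comb"),
        ]:
            out[f"auc_{name}"] = (
                float(roc_auc_score(y, report[col])) if len(np.unique(y)) == 2 else float("nan")
            )
        out["npv_comb"] = npv(report["p_comb"], y)
        return out

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Combined POD risk evaluation",
            "=" * 60,
            f"patients (train): {len(self.training_patient_ids)}   seed: {self.seed}",
            f"bagged estimators per ensemble: {self.ens_spec.n_estimators}",
            "",
            f"{'classifier':<16}{'train AUC':>10}{'g-mean th':>11}{'shift':>9}",
            "-" * 46,
        ]
        for name in ("patient", "patient_burst", "spec", "cov"):
            auc = self.training_auc.get(name, float("nan"))
            th = self.fusion.thresholds.get(name, float("nan"))
            sh = self.fusion.shifts.get(name, 0.0)
            th_s = f"{th:10.3f}" if th == th else f"{'--':>10}"
            sh_s = f"{sh:+9.3f}" if name in self.fusion.thresholds else f"{'--':>9}"
            lines.append(f"{name:<16}{auc:10.3f} {th_s}{sh_s}")
        lines += [
            "-" * 46,
            f"shift subset: {' + '.join(self.fusion.shift_subset)}",
            f"training AUC of p_comb: {self.fusion.training_comb_auc:.3f}",
            f"p_m override below {self.fusion.pm_cutoff:g} "
            f"(AUC floor {self.fusion.auc_floor:g}); call threshold 0.5",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        from .io import save_bundle

        save_bundle(self, path)
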