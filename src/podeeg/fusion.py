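"""Combining the three classifier probabilities into the final risk.

The combined risk is deliberately false-negative averse:

    p_comb = max(p_patient+burst, min(p_spec, p_cov))

so a patient is called low-risk only when the clinical classifier *and*
at least one of the two EEG classifiers agree.  Because the three
probabilities are averages of different things, each classifier first has
its g-mean-optimal training threshold shifted to 0.5
(``shift = 0.5 - th``); the shifts are applied either to all three
classifiers or to two of three, whichever subset maximizes the training
AUC of p_comb, and the frozen shifts are applied unchanged at test time.

To keep small probabilities informative, the plain mean p_m of the
classifiers with sufficient training AUC overrides the max/min rule
whenever p_m < 0.25.  The binary call threshold is fixed at 0.5, chosen
to keep the negative predictive value high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError

CLASSIFIERS = ("patient_burst", "spec", "cov")
#: subset preference order for exact AUC ties (determinism)
SHIFT_SUBSETS = (
    ("patient_burst", "spec", "cov"),
    ("patient_burst", "spec"),
    ("patient_burst", "cov"),
    ("spec", "cov"),
)


def gmean_threshold(probs, labels) -> float:
    """Threshold maximizing the g-mean sqrt(TPR * (1 - FPR)).

    Candidates are the midpoints between consecutive distinct sorted
    probabilities; a probability at or above the threshold is called
    positive.  Ties break toward the smallest threshold; if every
    probability is identical there is no informative threshold and 0.5 is
    returned.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        raise ContractError("gmean_threshold needs both classes")
    distinct = np.unique(probs)
    if distinct.size < 2:
        return 0.5
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    pos = labels == 1
    n_pos, n_neg = pos.sum(), (~pos).sum()
    calls = probs[None, :] >= candidates[:, None]
    tpr = (calls & pos).sum(axis=1) / n_pos
    fpr = (calls & ~pos).sum(axis=1) / n_neg
    g = np.sqrt(tpr * (1.0 - fpr))
    return float(candidates[int(np.argmax(g))])   # first max = smallest threshold


@dataclass
class FusionState:
    """Frozen threshold shifts and training diagnostics of the fusion."""

    thresholds: dict = field(default_factory=dict)    # classifier -> g-mean threshold
    shifts: dict = field(default_factory=dict)        # classifier -> 0.5 - th or 0
    shift_subset: tuple = SHIFT_SUBSETS[0]
    training_auc: dict = field(default_factory=dict)
    auc_floor: float = 0.55
    pm_cutoff: float = 0.25
    training_comb_auc: float = float("nan")


def _shifted(probs: np.ndarray, shift: float) -> np.ndarray:
    return np.clip(np.asarray(probs, dtype=float) + shift, 0.0, 1.0)


def combine(
    p_patient_burst,
    p_spec,
    p_cov,
    training_auc: dict,
    auc_floor: float = 0.55,
    pm_cutoff: float = 0.25,
):
    """Elementwise combined risk with the low-probability override.

    ``base = max(p_patient_burst, min(p_spec, p_cov))``; where the common
    average p_m of the classifiers whose training AUC reaches
    ``auc_floor`` falls below ``pm_cutoff``, p_comb = p_m instead.
    """
    p = {
        "patient_burst": np.atleast_1d(np.asarray(p_patient_burst, dtype=float)),
        "spec": np.atleast_1d(np.asarray(p_spec, dtype=float)),
        "cov": np.atleast_1d(np.asarray(p_cov, dtype=float)),
    }
    base = np.maximum(p["patient_burst"], np.minimum(p["spec"], p["cov"]))
    trusted = [c for c in CLASSIFIERS if training_auc.get(c, 0.0) >= auc_floor]
    if not trusted:
        warnings.warn("no classifier reached the AUC floor; override disabled")
        return base if base.size > 1 else float(base[0])
    p_m = np.mean([p[c] for c in trusted], axis=0)
    out = np.where(p_m < pm_cutoff, p_m, base)
    return out if out.size > 1 else float(out[0])


def apply_fusion(state: FusionState, p_patient_burst, p_spec, p_cov):
    """Apply frozen shifts and combine; returns (p_comb, shifted dict)."""
    shifted = {
        "patient_burst": _shifted(p_patient_burst, state.shifts.get("patient_burst", 0.0)),
        "spec": _shifted(p_spec, state.shifts.get("spec", 0.0)),
        "cov": _shifted(p_cov, state.shifts.get("cov", 0.0)),
    }
    p_comb = combine(
        shifted["patient_burst"],
        shifted["spec"],
        shifted["cov"],
        state.training_auc,
        state.auc_floor,
        state.pm_cutoff,
    )
    return p_comb, shifted


def select_shifts(
    p_patient_burst,
    p_spec,
    p_cov,
    labels,
    auc_floor: float = 0.55,
    pm_cutoff: float = 0.25,
) -> FusionState:
    """Choose the shift subset maximizing the training AUC of p_comb.

    Evaluates shifting all three classifiers and each two-of-three subset
    (the left-out shift set to 0); exact AUC ties resolve by the fixed
    preference order all > (patient, spec) > (patient, cov) > (spec, cov).
    """
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels, dtype=int)
    probs = {
        "patient_burst": np.asarray(p_patient_burst, dtype=float),
        "spec": np.asarray(p_spec, dtype=float),
        "cov": np.asarray(p_cov, dtype=float),
    }
    thresholds = {c: gmean_threshold(probs[c], labels) for c in CLASSIFIERS}
    training_auc = {c: float(roc_auc_score(labels, probs[c])) for c in CLASSIFIERS}

    best = None
    for subset in SHIFT_SUBSETS:
        shifts = {
            c: (0.5 - thresholds[c]) if c in subset else 0.0 for c in CLASSIFIERS
        }
        state = FusionState(
            thresholds=thresholds,
            shifts=shifts,
            shift_subset=subset,
            training_auc=training_auc,
            auc_floor=auc_floor,
            pm_cutoff=pm_cutoff,
        )
        p_comb, _ = apply_fusion(state, probs["patient_burst"], probs["spec"], probs["cov"])
        auc = float(roc_auc_score(labels, p_comb))
        state.training_comb_auc = auc
        if best is None or auc > best.training_comb_auc:   # strict: ties keep order
            best = state
    return best


def npv(p_comb, labels) -> float:
    """Negative predictive value TN / (TN + FN) with calls at
    p_comb >= 0.5; NaN (missing) when there is no negative call."""
    p_comb = np.asarray(p_comb, dtype=float)
    labels = np.asarray(labels, dtype=int)
    negative_call = p_comb < 0.5
    if not negative_call.any():
        return float("nan")
    tn = int(np.sum(negative_call & (labels == 0)))
    fn = int(np.sum(negative_call & (labels == 1)))
    return tn / (tn + fn)
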