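"""Balanced random forest on clinical (+ burst-suppression) features.

Each tree is grown on a bootstrap of the minority class plus an
equal-size random draw (with replacement) from the majority class, so the
expected per-tree class ratio is 1:1 regardless of cohort imbalance
(Chen & Breiman's balanced random forest).  The forest probability for a
patient is the plain mean of the per-tree class-1 probabilities.

Out-of-bag probabilities (trees whose draw excluded the patient) provide
an unbiased training-set estimate used for fusion threshold selection.

Clinical features: age, ASA score, operation length, benzodiazepine flag,
and one-hot induction / maintenance agents with fixed vocabularies; an
unseen category maps to "Other" so a frozen model never crashes on a new
cohort.  The ``patient+burstsupp`` feature set appends BSR and LSP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import ContractError

INDUCTION_VOCAB = ("Propofol", "Thiopental", "Etomidate", "Other")
MAINTENANCE_VOCAB = ("Propofol", "Desflurane", "Sevoflurane", "Isoflurane", "Other")
NUMERIC_COLS = ("age", "asa", "op_length_h", "benzodiazepine")
BURST_COLS = ("bsr", "lsp_s")


def _one_hot(values, vocab) -> np.ndarray:
    cols = []
    mapped = ["Other" if v not in vocab else v for v in values]
    for level in vocab:
        cols.append(np.asarray([v == level for v in mapped], dtype=float))
    return np.stack(cols, axis=1)


def encode_clinical(table: pd.DataFrame, with_burst: bool = False):
    """Encode a clinical table into a numeric design matrix.

    Returns (X, feature_names).  ``with_burst`` requires ``bsr`` and
    ``lsp_s`` columns.
    """
    missing = [c for c in NUMERIC_COLS if c not in table.columns]
    if missing:
        raise ContractError(f"clinical table missing columns: {missing}")
    parts = [table[list(NUMERIC_COLS)].to_numpy(dtype=float)]
    names = list(NUMERIC_COLS)
    parts.append(_one_hot(table["induction_agent"], INDUCTION_VOCAB))
    names += [f"induction={v}" for v in INDUCTION_VOCAB]
    parts.append(_one_hot(table["maintenance_agent"], MAINTENANCE_VOCAB))
    names += [f"maintenance={v}" for v in MAINTENANCE_VOCAB]
    if with_burst:
        missing = [c for c in BURST_COLS if c not in table.columns]
        if missing:
            raise ContractError(f"burst-suppression columns missing: {missing}")
        parts.append(table[list(BURST_COLS)].to_numpy(dtype=float))
        names += list(BURST_COLS)
    return np.concatenate(parts, axis=1), names


@dataclass
class BalancedRandomForest:
    """Random forest with per-tree balanced bootstrap sampling."""

    n_trees: int = 500
    max_features: str = "sqrt"
    random_state: int = 0
    trees: list = field(default_factory=list)
    tree_samples: list = field(default_factory=list)   # bootstrap indices per tree
    feature_names: list = field(default_factory=list)

    def fit(self, x: np.ndarray, y: np.ndarray, feature_names=None) -> "BalancedRandomForest":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ContractError(f"need two classes, got {list(classes)}")
        minority = classes[np.argmin([np.sum(y == c) for c in classes])]
        idx_minor = np.flatnonzero(y == minority)
        idx_major = np.flatnonzero(y != minority)
        rng = np.random.default_rng(self.random_state)
        self.trees, self.tree_samples = [], []
        n = len(idx_minor)
        for _ in range(self.n_trees):
            draw = np.concatenate(
                [
                    rng.choice(idx_minor, size=n, replace=True),
                    rng.choice(idx_major, size=n, replace=True),
                ]
            )
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(x[draw], y[draw])
            self.trees.append(tree)
            self.tree_samples.append(draw)
        self.feature_names = list(feature_names) if feature_names is not None else []
        self._classes = np.sort(classes)
        return self

    def _tree_proba(self, tree, x: np.ndarray) -> np.ndarray:
        proba = tree.predict_proba(x)
        col = {c: i for i, c in enumerate(tree.classes_)}
        return proba[:, col[1]] if 1 in col else np.zeros(len(x))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Mean over the trees' class-1 probabilities, in [0, 1];
        invariant to tree order."""
        if not self.trees:
            raise ContractError("forest is not fitted")
        x = np.asarray(x, dtype=float)
        return np.mean([self._tree_proba(t, x) for t in self.trees], axis=0)

    def oob_proba(self, x: np.ndarray) -> np.ndarray:
        """Out-of-bag probability per training row (NaN if a row was in
        every tree's draw, which is vanishingly rare)."""
        x = np.asarray(x, dtype=float)
        total = np.zeros(len(x))
        count = np.zeros(len(x))
        for tree, draw in zip(self.trees, self.tree_samples):
            out = np.ones(len(x), dtype=bool)
            out[np.unique(draw)] = False
            if out.any():
                total[out] += self._tree_proba(tree, x[out])
                count[out] += 1
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def train_balanced_rf(
    table: pd.DataFrame,
    labels,
    with_burst: bool = False,
    n_trees: int = 500,
    random_state: int = 0,
) -> BalancedRandomForest:
    x, names = encode_clinical(table, with_burst=with_burst)
    forest = BalancedRandomForest(n_trees=n_trees, random_state=random_state)
    return forest.fit(x, np.asarray(labels, dtype=int), feature_names=names)


def predict_rf(forest: BalancedRandomForest, table: pd.DataFrame) -> np.ndarray:
    with_burst = BURST_COLS[0] in forest.feature_names
    x, _ = encode_clinical(table, with_burst=with_burst)
    return forest.predict_proba(x)
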