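"""Feature-based document-level classification: balanced sampling,
decision-tree / random-forest wrappers, and balanced 10-fold cross-validation.

Document-level candidate sets are heavily imbalanced (most of the m x n pairs
are false), so both training and test portions of every fold are balanced by
randomly down-sampling negatives to the positive count.  Models are
scikit-learn CART trees / forests with default hyper-parameters, seeded for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .docfeatures import FEATURE_NAMES, DocCandidate, DocFeatureVector
from .evaluation import MetricReport, prf_from_predictions

MODEL_KINDS = ("decision_tree", "random_forest")


@dataclass
class LabeledFeatureSet:
    """Rows of (candidate, features, label) in the fixed feature order."""

    rows: list[tuple[DocCandidate, DocFeatureVector, bool]]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def matrix(self, feature_subset: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        names = list(self.feature_names)
        if feature_subset is None:
            cols = list(range(len(names)))
        else:
            unknown = set(feature_subset) - set(names)
            if unknown:
                raise ValueError(f"unknown feature names: {sorted(unknown)}")
            cols = [names.index(f) for f in feature_subset]
        X = np.asarray([row[1].as_tuple() for row in self.rows], dtype=float)
        y = np.asarray([row[2] for row in self.rows], dtype=int)
        if not cols:
            # empty feature subset: a constant column gives the model nothing
            # to split on, yielding the constant-prediction floor
            return np.zeros((len(self.rows), 1)), y
        if X.size == 0:
            return np.zeros((0, len(cols))), y
        return X[:, cols], y

    def __len__(self) -> int:
        return len(self.rows)


def balanced_sample(
    rows: Sequence[tuple[DocCandidate, DocFeatureVector, bool]], seed: int
) -> list[tuple[DocCandidate, DocFeatureVector, bool]]:
    """Keep all positives; sample negatives without replacement down to the
    positive count (all negatives kept when there are fewer).  Deterministic
    for a fixed seed; original row order is preserved."""
    pos_idx = [i for i, r in enumerate(rows) if r[2]]
    neg_idx = [i for i, r in enumerate(rows) if not r[2]]
    if not pos_idx:
        raise ValueError("balanced sampling requires at least one positive row")
    rng = np.random.default_rng(seed)
    if len(neg_idx) > len(pos_idx):
        neg_idx = list(rng.choice(neg_idx, size=len(pos_idx), replace=False))
    keep = sorted(pos_idx + list(neg_idx))
    return [rows[i] for i in keep]


@dataclass
class DocModel:
    """A fitted classifier over the fixed (or a subset) feature order."""

    estimator: object
    feature_subset: tuple[str, ...] | None = None

    def predict(self, features: LabeledFeatureSet) -> np.ndarray:
        X, _ = features.matrix(self.feature_subset)
        return self.estimator.predict(X).astype(bool)

    def predict_score(self, features: LabeledFeatureSet) -> np.ndarray:
        X, _ = features.matrix(self.feature_subset)
        return self.estimator.predict_proba(X)[:, 1]


def train_doc_model(
    features: LabeledFeatureSet,
    model_kind: str = "random_forest",
    seed: int = 0,
    feature_subset: Sequence[str] | None = None,
) -> DocModel:
    """Fit a CART decision tree or a random forest (library defaults, seeded)."""
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    X, y = features.matrix(feature_subset)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires rows of both classes")
    if model_kind == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed)
    else:
        est = RandomForestClassifier(random_state=seed)
    est.fit(X, y)
    return DocModel(est, tuple(feature_subset) if feature_subset is not None else None)


def cross_validate(
    features: LabeledFeatureSet,
    model_kind: str = "random_forest",
    folds: int = 10,
    seed: int = 0,
    feature_subset: Sequence[str] | None = None,
) -> tuple[MetricReport, list[MetricReport]]:
    """Stratified k-fold CV with per-fold balanced train and test sampling.

    Folds are assigned first (stratified so small sets keep both classes per
    fold), then each fold's training and test rows are independently balanced.
    Returns the fold-mean report and the per-fold list.
    """
    _, y = features.matrix()
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < folds or n_neg < folds:
        raise ValueError(
            f"need at least {folds} rows of each class, have {n_pos} positives / {n_neg} negatives"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports: list[MetricReport] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_rows = balanced_sample([features.rows[i] for i in train_idx], seed * 1000 + fold)
        test_rows = balanced_sample([features.rows[i] for i in test_idx], seed * 1000 + 500 + fold)
        model = train_doc_model(
            LabeledFeatureSet(train_rows, features.feature_names),
            model_kind, seed, feature_subset,
        )
        test_set = LabeledFeatureSet(test_rows, features.feature_names)
        pred = model.predict(test_set)
        truth = np.asarray([r[2] for r in test_rows], dtype=bool)
        reports.append(prf_from_predictions(truth, pred))
    mean = MetricReport.mean(reports)
    return mean, reports
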