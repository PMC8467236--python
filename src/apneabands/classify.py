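"""SVM and random-forest classification of the feature table, with the
accuracy / sensitivity / specificity metrics used in sleep-apnea screening.

"Positive" is the apnea class throughout: sensitivity = TP/(TP+FN) is the
fraction of apnea subjects detected, specificity = TN/(TN+FP) the fraction
of normal subjects correctly cleared.

SVMs see standardized features (mean/variance estimated on training data
only — energies span orders of magnitude and would otherwise dominate
kernel distances); the random forest consumes raw features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_COLUMNS

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "SVM_KERNELS",
    "SplitSpec",
    "ConfusionCounts",
    "Metrics",
    "CVResult",
    "split_dataset",
    "make_svm",
    "train_svm",
    "train_rf",
    "predict",
    "confusion_counts",
    "compute_metrics",
    "evaluate",
    "cross_validate",
]

POSITIVE_LABEL = "apnea"
NEGATIVE_LABEL = "normal"
SVM_KERNELS = ("linear", "rbf", "poly2", "poly3")


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out split: 90% training / 10% testing by default, stratified.

    Training takes floor(train_fraction * n) subjects per class, so an
    89-subject cohort (57 apnea / 32 normal) splits 79 / 10.
    """

    train_fraction: float = 0.9
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """Proportions in [0, 1]; undefined denominators surface as NaN, never 0."""

    accuracy: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity}


@dataclass
class CVResult:
    per_fold: list[Metrics]
    mean: Metrics


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in ("label", *FEATURE_COLUMNS) if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    return table[list(FEATURE_COLUMNS)].to_numpy(float), table["label"].to_numpy()


def split_dataset(features: pd.DataFrame,
                  spec: SplitSpec = SplitSpec()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic (seeded) stratified hold-out split of the feature table."""
    labels = features["label"]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError(f"need both classes to split, found only {classes}")
    rng = np.random.default_rng(spec.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    groups = [features.index.to_numpy()] if not spec.stratified else [
        features.index[labels == c].to_numpy() for c in classes
    ]
    for idx in groups:
        if spec.stratified and len(idx) < 2:
            raise ValueError("stratified splitting needs >= 2 samples per class")
        idx = idx[rng.permutation(len(idx))]
        n_train = int(math.floor(spec.train_fraction * len(idx)))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    train = features.loc[np.concatenate(train_idx)].sort_index()
    test = features.loc[np.concatenate(test_idx)].sort_index()
    return train, test


def make_svm(kernel: str = "poly2", C: float = 1.0, gamma: str | float = "scale",
             coef0: float = 1.0) -> Pipeline:
    """Standardizer + SVC for one of the four kernels (linear/rbf/poly2/poly3)."""
    if kernel not in SVM_KERNELS:
        raise ValueError(f"kernel must be one of {SVM_KERNELS}, got {kernel!r}")
    if kernel in ("poly2", "poly3"):
        svc = SVC(kernel="poly", degree=int(kernel[-1]), C=C, gamma=gamma, coef0=coef0)
    else:
        svc = SVC(kernel=kernel, C=C, gamma=gamma)
    return Pipeline([("scale", StandardScaler()), ("svc", svc)])


def train_svm(train: pd.DataFrame, kernel: str = "poly2", **params) -> Pipeline:
    """Fit an SVM on a feature table; deterministic for fixed input."""
    X, y = _xy(train)
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    model = make_svm(kernel, **params)
    return model.fit(X, y)


def train_rf(train: pd.DataFrame, n_trees: int = 150,
             seed: int = 0) -> tuple[RandomForestClassifier, float]:
    """Fit a random forest (150 trees, 2/3 in-bag) and return its OOB error."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X, y = _xy(train)
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    model = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, bootstrap=True,
        max_samples=2 / 3, random_state=seed,
    )
    model.fit(X, y)
    return model, float(1.0 - model.oob_score_)


def predict(model, table: pd.DataFrame) -> np.ndarray:
    X, _ = _xy(table) if "label" in table.columns else (
        table[list(FEATURE_COLUMNS)].to_numpy(float), None)
    return model.predict(X)


def confusion_counts(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionCounts:
    t = np.asarray(y_true) == POSITIVE_LABEL
    p = np.asarray(y_pred) == POSITIVE_LABEL
    return ConfusionCounts(
        tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)),
    )


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy (TP+TN)/total, sensitivity TP/(TP+FN), specificity TN/(TN+FP)."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    sens = spec = math.nan
    if c.tp + c.fn > 0:
        sens = c.tp / (c.tp + c.fn)
    else:
        warnings.warn("no positive samples; sensitivity undefined (NaN)", stacklevel=2)
    if c.tn + c.fp > 0:
        spec = c.tn / (c.tn + c.fp)
    else:
        warnings.warn("no negative samples; specificity undefined (NaN)", stacklevel=2)
    return Metrics(accuracy=(c.tp + c.tn) / c.total, sensitivity=sens, specificity=spec)


def evaluate(model, test: pd.DataFrame) -> tuple[ConfusionCounts, Metrics]:
    """Confusion counts and metrics of a fitted model on a held-out table."""
    _, y = _xy(test)
    counts = confusion_counts(y, predict(model, test))
    return counts, compute_metrics(counts)


def cross_validate(features: pd.DataFrame,
                   model_factory: Callable[[], object] | None = None,
                   k: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation; per-fold and mean metrics.

    ``model_factory`` returns a fresh unfitted estimator per fold (defaults
    to the polynomial-order-2 SVM). Deterministic for a fixed seed.
    """
    if model_factory is None:
        model_factory = make_svm
    X, y = _xy(features)
    counts = pd.Series(y).value_counts()
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for tr, te in skf.split(X, y):
        model = clone(model_factory()).fit(X[tr], y[tr])
        cc = confusion_counts(y[te], model.predict(X[te]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-class folds at extreme k
            per_fold.append(compute_metrics(cc))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = Metrics(
            accuracy=float(np.mean([m.accuracy for m in per_fold])),
            sensitivity=float(np.nanmean([m.sensitivity for m in per_fold])),
            specificity=float(np.nanmean([m.specificity for m in per_fold])),
        )
    return CVResult(per_fold=per_fold, mean=mean)
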