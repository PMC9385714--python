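"""Neutral/deleterious sequence classifiers with ROC threshold tuning.

Variants are labelled neutral (RA >= 0.2) or deleterious (RA < 0.2) and
one-hot encoded (position-major, 4 bases, so a 35-nt core becomes a 1x140
binary vector). Five model families of increasing capacity are supported:
logistic regression and a linear-kernel SVM as linear baselines, k-nearest
neighbours and gradient-boosted trees as nonlinear models, and a multilayer
perceptron (dense 128/64/32 ReLU layers) that can in principle capture
higher-order epistasis. Class imbalance is handled only by moving the
decision threshold to the point on the validation ROC curve maximizing the
geometric mean sqrt(TPR * (1 - FPR)), not by reweighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from ribonet.activity_quant import NeutralityConfig
from ribonet.sequence_core import Genotype, one_hot_matrix

FAMILIES = (
    "logistic_regression",
    "k_nearest_neighbors",
    "linear_svm",
    "gradient_boosted_trees",
    "multilayer_perceptron",
)

#: pinned "default" hyperparameters so results do not drift across versions
PINNED_HYPERPARAMETERS: dict[str, dict] = {
    "logistic_regression": {"C": 1.0, "max_iter": 1000},  # ridge-penalized default
    "k_nearest_neighbors": {"n_neighbors": 5},
    "linear_svm": {"kernel": "linear", "C": 1.0, "probability": True},
    "gradient_boosted_trees": {"max_depth": 10, "n_estimators": 100},
    "multilayer_perceptron": {
        "hidden_layer_sizes": (128, 64, 32),
        "activation": "relu",
        "solver": "adam",
        "learning_rate_init": 0.005,
        "batch_size": 1024,
        "max_iter": 100,
    },
}


@dataclass
class EncodedDataset:
    """One-hot features, neutrality labels and a 70/30 train/test split."""

    X: np.ndarray
    y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    sequences: list[Genotype] = field(default_factory=list)

    @property
    def X_train(self) -> np.ndarray:
        return self.X[self.train_idx]

    @property
    def y_train(self) -> np.ndarray:
        return self.y[self.train_idx]

    @property
    def X_test(self) -> np.ndarray:
        return self.X[self.test_idx]

    @property
    def y_test(self) -> np.ndarray:
        return self.y[self.test_idx]


def make_dataset(
    activity_table: pd.DataFrame,
    cfg: NeutralityConfig | None = None,
    rng: np.random.Generator | int | None = None,
    test_fraction: float = 0.3,
) -> EncodedDataset:
    """Encode an activity table and split 70/30 by a seeded shuffle.

    Labels are 1 (neutral) iff RA_mean >= threshold — the comparison is
    inclusive, so RA exactly at the threshold is neutral.
    """
    if len(activity_table) == 0:
        raise ValueError("empty activity table")
    cfg = cfg or NeutralityConfig()
    seqs = list(activity_table["sequence"])
    X = one_hot_matrix(seqs)
    y = (activity_table["RA_mean"].to_numpy() >= cfg.threshold).astype(int)
    rng = np.random.default_rng(rng)
    idx = rng.permutation(len(y))
    n_test = int(round(test_fraction * len(y)))
    return EncodedDataset(
        X=X, y=y, train_idx=idx[n_test:], test_idx=idx[:n_test], sequences=seqs
    )


def _base_estimator(family: str, hyperparameters: dict | None, random_state):
    params = dict(PINNED_HYPERPARAMETERS[family])
    if hyperparameters:
        params.update(hyperparameters)
    if family == "logistic_regression":
        return LogisticRegression(**params)
    if family == "k_nearest_neighbors":
        return KNeighborsClassifier(**params)
    if family == "linear_svm":
        return SVC(random_state=random_state, **params)
    if family == "gradient_boosted_trees":
        return GradientBoostingClassifier(random_state=random_state, **params)
    if family == "multilayer_perceptron":
        return MLPClassifier(random_state=random_state, **params)
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def tune_threshold_roc(y_true: np.ndarray, proba: np.ndarray) -> float:
    """Decision threshold maximizing the ROC geometric mean.

    Scans the candidate thresholds of the ROC curve and returns the one
    with the largest sqrt(TPR * (1 - FPR)); ties resolve to the lowest
    threshold. Requires both classes in ``y_true``.
    """
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("threshold tuning needs both classes")
    fpr, tpr, thresholds = roc_curve(y_true, proba)
    gmean = np.sqrt(tpr * (1.0 - fpr))
    best = gmean.max()
    candidates = thresholds[np.isclose(gmean, best)]
    t = float(candidates.min())
    return min(max(t, 1e-9), 1.0)  # roc_curve pads with threshold > 1


class NeutralityClassifier(ClassifierMixin, BaseEstimator):
    """Binary neutral/deleterious classifier over one-hot sequence encodings.

    A sklearn-compatible estimator. ``fit`` carves out a validation
    fraction (10% by default) from the training data, fits the chosen
    family on the remainder, and tunes the decision threshold on the
    carve-out via the ROC geometric mean; set ``tune_threshold=False`` to
    keep the default 0.5.

    Parameters
    ----------
    family:
        One of ``logistic_regression``, ``k_nearest_neighbors``,
        ``linear_svm``, ``gradient_boosted_trees``,
        ``multilayer_perceptron``.
    hyperparameters:
        Overrides merged into the pinned per-family defaults.
    validation_fraction:
        Fraction of the training set held out for threshold tuning.
    """

    def __init__(
        self,
        family: str = "multilayer_perceptron",
        hyperparameters: dict | None = None,
        tune_threshold: bool = True,
        validation_fraction: float = 0.1,
        random_state: int | None = None,
    ):
        self.family = family
        self.hyperparameters = hyperparameters
        self.tune_threshold = tune_threshold
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        est = _base_estimator(self.family, self.hyperparameters, self.random_state)
        if self.tune_threshold:
            X_fit, X_val, y_fit, y_val = train_test_split(
                X,
                y,
                test_size=self.validation_fraction,
                random_state=self.random_state,
                stratify=y,
            )
            est.fit(X_fit, y_fit)
            if len(np.unique(y_val)) < 2:
                # carve-out too small to hold both classes; keep the default
                self.decision_threshold_ = 0.5
            else:
                self.decision_threshold_ = tune_threshold_roc(
                    y_val, est.predict_proba(X_val)[:, 1]
                )
        else:
            est.fit(X, y)
            self.decision_threshold_ = 0.5
        self.model_ = est
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.model_.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)[:, 1]
        return (proba >= self.decision_threshold_).astype(int)

    def predict_neutral(self, sequences: Sequence[Genotype]) -> np.ndarray:
        """Predict the neutrality of raw sequences (boolean array)."""
        return self.predict(one_hot_matrix(list(sequences))).astype(bool)


def train(
    family: str,
    data: EncodedDataset,
    rng_seed: int | None = None,
    **kwargs,
) -> NeutralityClassifier:
    """Fit a classifier of the given family on the dataset's training split."""
    clf = NeutralityClassifier(family=family, random_state=rng_seed, **kwargs)
    return clf.fit(data.X_train, data.y_train)


@dataclass
class EvalReport:
    """Confusion counts and the derived classification metrics.

    ``precision`` is the fraction of neutral predictions that are truly
    neutral; ``recall`` the fraction of truly neutral variants recovered;
    ``null_accuracy`` the accuracy of always predicting the majority
    class. Metrics undefined because of an empty denominator are NaN with
    ``degenerate`` set.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    accuracy: float
    f1: float
    null_accuracy: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "null_accuracy": self.null_accuracy,
        }


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """Metrics from labels and hard predictions."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    accuracy = (tp + tn) / len(y_true)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (tp + fp) and (tp + fn) and (precision + recall) > 0
        else float("nan")
    )
    counts = np.bincount(y_true, minlength=2)
    null_accuracy = counts.max() / len(y_true)
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        f1=f1,
        null_accuracy=null_accuracy,
        degenerate=degenerate,
    )


def evaluate(model: NeutralityClassifier, X_test, y_test) -> EvalReport:
    """Evaluate a fitted classifier on a held-out split."""
    return evaluate_predictions(y_test, model.predict(X_test))


def cross_validate(
    family: str,
    data: EncodedDataset,
    folds: int = 10,
    rng_seed: int | None = None,
    **kwargs,
) -> list[EvalReport]:
    """Seeded stratified k-fold cross-validation; one report per fold."""
    y = data.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError("too few examples per class for the requested folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    reports = []
    template = NeutralityClassifier(family=family, random_state=rng_seed, **kwargs)
    for train_idx, test_idx in skf.split(data.X, y):
        model = clone(template).fit(data.X[train_idx], y[train_idx])
        reports.append(evaluate(model, data.X[test_idx], y[test_idx]))
    return reports


def summarize_reports(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Mean +/- sd of each metric across folds or seeds."""
    df = pd.DataFrame([r.as_dict() for r in reports])
    return df.agg(["mean", "std"])
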