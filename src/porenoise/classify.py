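"""Logistic-regression wettedness classification and evaluation protocols.

The binary target is the pore state: wetted (y = 0) versus unwetted
(y = 1, the positive class — the rare, defective state the screen must
catch).  Features are standardized with training-fold statistics only and
fed to an L2-penalized logistic regression

    P(y = 1 | x) = 1 / (1 + exp(-(beta0 + beta^T z))),  z = (x - mu) / sd

with fixed hyperparameters (C = 0.60, tolerance 1e-12, second-order
Newton-Cholesky solver, iteration cap 100,000) and a 0.5 decision
threshold.  Evaluation protocols: stratified group k-fold CV (groups =
pore-experiment combinations, so no pore-experiment straddles folds),
leave-one-voltage-out generalization, transfer to an independent feature
table, and exhaustive feature-subset search ranked by median F1.

Metrics are reported in percent for the unwetted class (precision,
recall, F1) plus specificity for the wetted class and overall accuracy;
zero-denominator metrics are NaN and excluded from medians.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_HYPERPARAMS",
    "ClassifierModel",
    "EvaluationReport",
    "train_logistic",
    "predict_wettedness",
    "stratified_group_kfold",
    "metrics_from_confusion",
    "evaluate_split",
    "cross_validate",
    "leave_one_voltage_out",
    "exhaustive_feature_search",
]

DEFAULT_HYPERPARAMS = {
    "C": 0.60,
    "tol": 1e-12,
    "solver": "newton-cholesky",
    "max_iter": 100_000,
}

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


def _as_binary_labels(labels) -> np.ndarray:
    """Map labels to y: unwetted -> 1 (positive class), wetted -> 0."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "SU O".replace(" ", ""):
        known = {"wetted": 0, "unwetted": 1}
        bad = set(np.unique(arr)) - set(known)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected wetted/unwetted")
        return np.array([known[str(v)] for v in arr], dtype=int)
    return arr.astype(int)


@dataclass
class ClassifierModel:
    """A trained wettedness classifier: feature subset, training-data
    standardization, logistic weights and hyperparameters."""

    feature_subset: tuple[str, ...]
    scaling_mean: np.ndarray
    scaling_sd: np.ndarray
    weights: np.ndarray
    intercept: float
    hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMS))
    decision_threshold: float = 0.5

    def __post_init__(self):
        self.scaling_mean = np.asarray(self.scaling_mean, dtype=float)
        self.scaling_sd = np.asarray(self.scaling_sd, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.feature_subset)
        if not (self.weights.size == self.scaling_mean.size == self.scaling_sd.size == n):
            raise ValueError("scaling/weight lengths must match the feature subset")
        if np.any(self.scaling_sd <= 0):
            raise ValueError("scaling SDs must be positive")

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_subset if f not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        X = features.loc[:, list(self.feature_subset)].to_numpy(dtype=float)
        z = (X - self.scaling_mean) / self.scaling_sd
        return self.intercept + z @ self.weights


def train_logistic(
    features: pd.DataFrame,
    labels,
    subset: tuple[str, ...],
    hyperparams: dict | None = None,
) -> ClassifierModel:
    """Fit the standardizer and L2-penalized logistic regression.

    Standardization parameters come from the training data only;
    training is deterministic for fixed input.
    """
    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    y = _as_binary_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("training requires samples of both classes")
    X = features.loc[:, list(subset)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError(f"non-finite values in training features {tuple(subset)}")
    scaler = StandardScaler().fit(X)
    clf = LogisticRegression(  # default penalty: L2 with strength 1/C
        C=hp["C"],
        tol=hp["tol"],
        solver=hp["solver"],
        max_iter=hp["max_iter"],
    ).fit(scaler.transform(X), y)
    return ClassifierModel(
        feature_subset=tuple(subset),
        scaling_mean=scaler.mean_,
        scaling_sd=scaler.scale_,
        weights=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        hyperparams=hp,
    )


def predict_wettedness(
    model: ClassifierModel, features: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment unwetted probability and predicted label.

    The call is "unwetted" iff P(y=1) >= the decision threshold.
    """
    logit = model.decision_function(features)
    prob = 1.0 / (1.0 + np.exp(-logit))
    calls = np.where(prob >= model.decision_threshold, "unwetted", "wetted")
    return prob, calls


def stratified_group_kfold(labels, groups, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold index per sample: groups never straddle folds, class balance
    as close to global as the group sizes allow; deterministic per seed."""
    y = _as_binary_labels(labels)
    groups = np.asarray(groups)
    if np.unique(groups).size < k:
        raise ValueError(f"need at least k={k} groups, got {np.unique(groups).size}")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.full(y.size, -1, dtype=int)
    for i, (_, test_idx) in enumerate(splitter.split(np.zeros((y.size, 1)), y, groups)):
        folds[test_idx] = i
    return folds


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Percent metrics from confusion counts; undefined ratios are NaN."""

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else np.nan

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = np.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": ratio(tp + tn, tp + fp + fn + tn),
        "precision": precision,
        "recall": recall,
        "specificity": ratio(tn, tn + fp),
        "f1": f1,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }


def evaluate_split(model: ClassifierModel, features: pd.DataFrame, labels) -> dict:
    """Confusion-count metrics of a trained model on one test split."""
    y = _as_binary_labels(labels)
    _, calls = predict_wettedness(model, features)
    pred = (calls == "unwetted").astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    return metrics_from_confusion(tp, fp, fn, tn)


@dataclass
class EvaluationReport:
    """Per-fold metrics plus aggregate medians and quartiles."""

    per_fold: pd.DataFrame  # one row per fold, METRIC_NAMES + confusion counts
    models: list = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        """Median and 25th/75th percentiles per metric, NaN folds excluded."""
        rows = []
        for m in METRIC_NAMES:
            vals = self.per_fold[m].to_numpy(dtype=float)
            ok = vals[np.isfinite(vals)]
            n_undef = int(np.sum(~np.isfinite(vals)))
            if n_undef:
                logger.info("metric %s undefined in %d fold(s)", m, n_undef)
            if ok.size:
                q25, med, q75 = np.percentile(ok, [25, 50, 75])
            else:
                q25 = med = q75 = np.nan
            rows.append({"metric": m, "median": med, "q25": q25, "q75": q75,
                         "n_folds": int(ok.size), "n_undefined": n_undef})
        return pd.DataFrame(rows).set_index("metric")

    def summary(self) -> str:
        agg = self.aggregate()
        lines = ["Classifier evaluation (%, median [25th-75th percentile])", "-" * 56]
        for m, row in agg.iterrows():
            lines.append(
                f"{m:<12} {row['median']:7.2f} [{row['q25']:.2f}-{row['q75']:.2f}]"
                + (f"  ({row['n_undefined']:.0f} undefined)" if row["n_undefined"] else "")
            )
        return "\n".join(lines)


def cross_validate(
    features: pd.DataFrame,
    labels,
    groups,
    subset: tuple[str, ...],
    k: int = 10,
    seed: int = 0,
    hyperparams: dict | None = None,
    folds: np.ndarray | None = None,
    keep_models: bool = False,
) -> EvaluationReport:
    """Stratified group k-fold cross-validation.

    Standardization and weights are refit on each training fold; the
    report holds per-fold metrics and their medians/quartiles.
    """
    y = _as_binary_labels(labels)
    if folds is None:
        folds = stratified_group_kfold(y, groups, k=k, seed=seed)
    rows, models = [], []
    for fold in np.unique(folds):
        train, test = folds != fold, folds == fold
        model = train_logistic(features.loc[train], y[train], subset, hyperparams)
        rows.append({"fold": int(fold), **evaluate_split(model, features.loc[test], y[test])})
        if keep_models:
            models.append(model)
    return EvaluationReport(per_fold=pd.DataFrame(rows).set_index("fold"), models=models)


def leave_one_voltage_out(
    features: pd.DataFrame,
    labels,
    groups,
    subset: tuple[str, ...],
    voltages=None,
    hyperparams: dict | None = None,
) -> dict[float, EvaluationReport]:
    """Train on all but one applied voltage, test on the held-out one.

    Returns one single-split report per voltage.  A held-out voltage with
    only one class yields NaN markers for the undefined metrics rather
    than an error.
    """
    v = np.asarray(features["V"] if voltages is None else voltages, dtype=float)
    y = _as_binary_labels(labels)
    distinct = np.unique(v)
    if distinct.size < 2:
        raise ValueError("leave-one-voltage-out requires at least two distinct voltages")
    out: dict[float, EvaluationReport] = {}
    for held in distinct:
        train, test = v != held, v == held
        model = train_logistic(features.loc[train], y[train], subset, hyperparams)
        row = {"fold": 0, **evaluate_split(model, features.loc[test], y[test])}
        out[float(held)] = EvaluationReport(
            per_fold=pd.DataFrame([row]).set_index("fold"), models=[model]
        )
    return out


def exhaustive_feature_search(
    features: pd.DataFrame,
    labels,
    groups,
    candidates,
    k: int = 10,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> pd.DataFrame:
    """Evaluate every nonempty candidate subset by cross-validated median F1.

    All 2^n - 1 subsets share one fold assignment and fixed hyperparameters.
    Ranking: median F1 descending, ties broken toward fewer features, then
    lexicographically by subset.
    """
    candidates = tuple(candidates)
    missing = [c for c in candidates if c not in features.columns]
    if missing:
        raise ValueError(f"candidate features absent from the table: {missing}")
    y = _as_binary_labels(labels)
    folds = stratified_group_kfold(y, groups, k=k, seed=seed)
    rows = []
    for r in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            report = cross_validate(
                features, y, groups, subset, k=k, seed=seed,
                hyperparams=hyperparams, folds=folds,
            )
            agg = report.aggregate()
            rows.append(
                {
                    "subset": subset,
                    "n_features": r,
                    "median_f1": agg.loc["f1", "median"],
                    "median_recall": agg.loc["recall", "median"],
                    "median_accuracy": agg.loc["accuracy", "median"],
                }
            )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["median_f1", "n_features", "subset"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
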