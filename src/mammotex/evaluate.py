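"""Random-forest training and repeated cross-validated evaluation.

The classifier is a random forest with 100 trees and at most 20 candidate
features per split (clipped to the number of selected features).  Evaluation
is repeated stratified 10-fold cross-validation: in every training fold a
feature ranking (filter or embedded) is recomputed from that fold alone — the
test fold never touches selection or training, so there is no selection
leakage — the forest is trained on the top-k features, and the test-fold
vote fractions are pooled per round before computing AUC, accuracy,
sensitivity and specificity.  Summaries are medians with 25th–75th percentile
intervals across rounds; methods are compared metric-by-metric with the
rank-sum test under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import selection
from .selection import FeatureRanking

METRICS = ("auc", "accuracy", "sensitivity", "specificity")


@dataclass
class ForestParams:
    n_trees: int = 100
    max_features_per_split: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_features_per_split < 1:
            raise ValueError("max_features_per_split must be >= 1")


def train_forest(X: np.ndarray, y: np.ndarray, params: ForestParams) -> RandomForestClassifier:
    """Fit the forest; vote fractions come out of :func:`predict_proba`.

    Trees are grown to purity, so the ensemble probability equals the
    fraction of trees voting for the positive class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("training set needs >= 2 samples of each of two classes")
    forest = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=min(params.max_features_per_split, X.shape[1]),
        random_state=params.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def predict_proba(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Positive-class score in [0, 1] for each row."""
    return model.predict_proba(np.asarray(X, dtype=float))[:, 1]


@dataclass
class BinaryMetrics:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


def binary_metrics(y_true, scores, threshold: float = 0.5) -> BinaryMetrics:
    """AUC (rank statistic, ties get half credit) plus threshold metrics,
    all in percent.  Positive class is label 1 (the pathological class)."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size != 2:
        raise ValueError("AUC undefined: y_true must contain both classes")
    auc = 100.0 * roc_auc_score(y, s)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return BinaryMetrics(
        auc=auc,
        accuracy=100.0 * (tp + tn) / y.size,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
    )


@dataclass
class CVReport:
    """Per-round pooled metrics and the per-fold rankings that produced them."""

    method: str
    k_features: int
    rounds: int
    folds: int
    seed: int
    per_round: pd.DataFrame  # columns = METRICS, one row per round, in %
    rankings: list[FeatureRanking] = field(default_factory=list)

    def summary(self, quantiles: tuple[float, float] = (0.25, 0.75)) -> pd.DataFrame:
        """Median and dispersion interval (default interquartile) per metric."""
        rows = {}
        for m in METRICS:
            vals = self.per_round[m]
            rows[m] = {
                "median": float(vals.median()),
                "lo": float(vals.quantile(quantiles[0])),
                "hi": float(vals.quantile(quantiles[1])),
            }
        return pd.DataFrame(rows).T

    def selection_frequency(self, k: int | None = None) -> selection.SelectionFrequencyTable:
        table = selection.topk_frequency(self.rankings, k or self.k_features)
        return selection.frequency_null_test(table)


def _sub_seed(master: int, *path: int) -> int:
    return int(np.random.SeedSequence([master, *path]).generate_state(1)[0] % 2**31)


def _rank(features: pd.DataFrame, y, method: str, seed: int,
          forest_params: ForestParams) -> FeatureRanking:
    if method == "filter":
        return selection.filter_rank(features, y)
    if method == "embedded":
        return selection.embedded_rank(
            features, y,
            n_trees=forest_params.n_trees,
            max_features_per_split=forest_params.max_features_per_split,
            seed=seed,
        )
    raise ValueError(f"unknown selection method {method!r}")


def repeated_cv(
    features: pd.DataFrame,
    labels,
    method: str = "embedded",
    k_features: int = 2,
    rounds: int = 100,
    folds: int = 10,
    seed: int = 0,
    forest_params: ForestParams | None = None,
    threshold: float = 0.5,
) -> CVReport:
    """Repeated stratified k-fold cross-validation with in-fold selection.

    Test-fold scores are pooled within each round; metrics are computed once
    per round on the pooled scores.  All sub-seeds (fold shuffling, embedded
    ranking, forest training) derive from ``seed`` via a counter, so a run is
    exactly reproducible.
    """
    fp = forest_params or ForestParams()
    y = np.asarray(labels).astype(int)
    if not (1 <= k_features <= features.shape[1]):
        raise ValueError(f"k_features must be in [1, {features.shape[1]}]")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    if counts.min() < folds:
        raise ValueError(
            f"stratified {folds}-fold CV needs >= {folds} samples per class, "
            f"got {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    X = features.to_numpy(dtype=float)
    rows = []
    rankings: list[FeatureRanking] = []
    for rnd in range(rounds):
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=_sub_seed(seed, rnd)
        )
        pooled_scores = np.empty(y.size)
        for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
            train_feats = features.iloc[train_idx]
            ranking = _rank(
                train_feats, y[train_idx], method,
                _sub_seed(seed, rnd, fold, 0), fp
            )
            rankings.append(ranking)
            selected = ranking.top(k_features)
            model = train_forest(
                train_feats[selected].to_numpy(dtype=float),
                y[train_idx],
                ForestParams(fp.n_trees, fp.max_features_per_split,
                             _sub_seed(seed, rnd, fold, 1)),
            )
            pooled_scores[test_idx] = predict_proba(
                model, features.iloc[test_idx][selected].to_numpy(dtype=float)
            )
        rows.append(binary_metrics(y, pooled_scores, threshold).as_dict())
    return CVReport(
        method=method, k_features=k_features, rounds=rounds, folds=folds,
        seed=seed, per_round=pd.DataFrame(rows, columns=list(METRICS)),
        rankings=rankings,
    )


@dataclass
class SweepResult:
    method: str
    k_grid: list[int]
    median_accuracy: dict[int, float]
    median_auc: dict[int, float]
    best_k: int
    reports: dict[int, CVReport]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_grid,
                "median_accuracy": [self.median_accuracy[k] for k in self.k_grid],
                "median_auc": [self.median_auc[k] for k in self.k_grid],
            }
        )


def feature_count_sweep(
    features: pd.DataFrame,
    labels,
    method: str = "embedded",
    k_grid: list[int] | None = None,
    rounds: int = 100,
    folds: int = 10,
    seed: int = 0,
    forest_params: ForestParams | None = None,
) -> SweepResult:
    """Median accuracy as a function of the number of selected features.

    Each k runs a full :func:`repeated_cv` with the same master seed, so the
    k = n_features point coincides exactly with no selection at all.  The
    best k is the smallest argmax of the median accuracy.
    """
    k_grid = sorted(k_grid or range(1, features.shape[1] + 1))
    if not k_grid or k_grid[0] < 1 or k_grid[-1] > features.shape[1]:
        raise ValueError(f"k_grid must lie within [1, {features.shape[1]}]")
    reports = {
        k: repeated_cv(features, labels, method, k, rounds, folds, seed, forest_params)
        for k in k_grid
    }
    med_acc = {k: float(r.per_round["accuracy"].median()) for k, r in reports.items()}
    med_auc = {k: float(r.per_round["auc"].median()) for k, r in reports.items()}
    best_k = max(k_grid, key=lambda k: (med_acc[k], -k))
    return SweepResult(method, k_grid, med_acc, med_auc, best_k, reports)


def compare_methods(
    report_a: CVReport, report_b: CVReport, n_comparisons: int = 1
) -> dict[str, float]:
    """Per-metric rank-sum p-values between two CV reports, Bonferroni-scaled.

    Raw two-sided p-values are multiplied by ``n_comparisons`` and capped at 1.
    """
    if report_a.rounds != report_b.rounds:
        raise ValueError("reports must have the same number of rounds")
    out = {}
    for m in METRICS:
        a = report_a.per_round[m].to_numpy()
        b = report_b.per_round[m].to_numpy()
        if np.array_equal(a, b) or (np.unique(np.concatenate([a, b])).size == 1):
            p = 1.0
        else:
            _, p = selection.wmw_test(a, b)
        out[m] = min(1.0, p * n_comparisons)
    return out
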