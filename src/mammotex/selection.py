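"""Filter and embedded feature ranking, top-k selection frequencies and the
null-model significance test.

Two rankings of the 50 features are supported:

* **filter** — each feature is scored by the two-sided Wilcoxon–Mann–Whitney
  (rank-sum) test between the two classes; features are ordered by ascending
  p-value, most discriminating first.  The ranking depends only on within-
  feature ranks, so it is invariant to any strictly monotone transform.
* **embedded** — features are scored by mean decrease in Gini impurity over a
  random-forest ensemble and ordered by descending importance.

For rankings recomputed across cross-validation folds, the fraction of
rankings placing a feature in the top k is compared with the exchangeable
null in which every ranking is an independent uniform permutation, so each
feature lands in the top k with probability k / n_features; the per-feature
p-value is the doubled binomial tail (capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

EXACT_MAX_N = 20  # combined sample size up to which the exact WMW null is used


def wmw_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``sample_a``.
    The exact null distribution is used for combined n <= 20 without ties;
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class FeatureRanking:
    """An ordered feature ranking: most informative first.

    ``scores`` is aligned with ``features`` and holds the two-sided p-value
    (filter) or the Gini importance (embedded).
    """

    method: str
    features: list[str]
    scores: list[float]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("filter", "embedded"):
            raise ValueError(f"method must be 'filter' or 'embedded', got {self.method!r}")
        if len(self.features) != len(set(self.features)):
            raise ValueError("duplicate feature names in ranking")
        if len(self.scores) != len(self.features):
            raise ValueError("scores must align with features")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ranking scores must be finite")

    def top(self, k: int) -> list[str]:
        return self.features[:k]


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    return classes


def filter_rank(features: pd.DataFrame, labels) -> FeatureRanking:
    """Rank features by ascending two-sided WMW p-value.

    Ties are broken by the column order of ``features`` (the frozen schema
    order when the full table is passed), via a stable sort.
    """
    y = np.asarray(labels)
    classes = _check_two_classes(y)
    mask = y == classes[0]
    pvals = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.all(x == x[0]):
            pvals.append(1.0)  # constant feature carries no information
        else:
            pvals.append(wmw_test(x[mask], x[~mask])[1])
    order = np.argsort(pvals, kind="stable")
    return FeatureRanking(
        "filter",
        [features.columns[i] for i in order],
        [pvals[i] for i in order],
    )


def embedded_rank(
    features: pd.DataFrame,
    labels,
    n_trees: int = 100,
    max_features_per_split: int = 20,
    seed: int = 0,
) -> FeatureRanking:
    """Rank features by mean decrease in Gini impurity in a random forest."""
    y = np.asarray(labels)
    _check_two_classes(y)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(max_features_per_split, features.shape[1]),
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(features.to_numpy(dtype=float), y)
    importances = forest.feature_importances_
    order = np.argsort(-importances, kind="stable")
    return FeatureRanking(
        "embedded",
        [features.columns[i] for i in order],
        [float(importances[i]) for i in order],
        seed=seed,
    )


@dataclass
class SelectionFrequencyTable:
    """Per-feature top-k selection frequencies (%) over a set of rankings."""

    k: int
    n_rankings: int
    frequency: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> list[str]:
        """Features whose top-k frequency departs from the uniform null,
        ordered by descending frequency (ties by name)."""
        if not self.p_values:
            raise ValueError("run frequency_null_test first")
        hits = [f for f, p in self.p_values.items() if p <= alpha]
        return sorted(hits, key=lambda f: (-self.frequency[f], f))


def topk_frequency(rankings: list[FeatureRanking], k: int) -> SelectionFrequencyTable:
    """Percentage of rankings in which each feature appears in the first k."""
    if not rankings:
        raise ValueError("need at least one ranking")
    names = set(rankings[0].features)
    if not (1 <= k <= len(names)):
        raise ValueError(f"k must be in [1, {len(names)}], got {k}")
    counts = dict.fromkeys(rankings[0].features, 0)
    for rk in rankings:
        if set(rk.features) != names:
            raise ValueError("rankings cover inconsistent feature sets")
        for f in rk.top(k):
            counts[f] += 1
    freq = {f: 100.0 * c / len(rankings) for f, c in counts.items()}
    return SelectionFrequencyTable(k=k, n_rankings=len(rankings), frequency=freq)


def frequency_null_test(
    table: SelectionFrequencyTable, n_rankings: int | None = None,
    n_features: int | None = None,
) -> SelectionFrequencyTable:
    """Two-sided binomial test of each top-k frequency against the uniform
    null (inclusion probability k / n_features per ranking).

    The p-value is twice the smaller binomial tail, capped at 1; it is stored
    on the table, which is returned for chaining.
    """
    n = n_rankings if n_rankings is not None else table.n_rankings
    m = n_features if n_features is not None else len(table.frequency)
    p_null = table.k / m
    pvals = {}
    for f, freq in table.frequency.items():
        x = int(round(freq / 100.0 * n))
        upper = stats.binom.sf(x - 1, n, p_null)  # P(X >= x)
        lower = stats.binom.cdf(x, n, p_null)     # P(X <= x)
        pvals[f] = min(1.0, 2.0 * min(upper, lower))
    table.p_values = pvals
    return table


def frequency_report(table: SelectionFrequencyTable, alpha: float = 0.05) -> pd.DataFrame:
    """Report of significantly-selected features with frequencies to 2 dp."""
    rows = [
        {"feature": f, "freq_pct": round(table.frequency[f], 2),
         "p_value": table.p_values[f]}
        for f in table.significant(alpha)
    ]
    return pd.DataFrame(rows, columns=["feature", "freq_pct", "p_value"])
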