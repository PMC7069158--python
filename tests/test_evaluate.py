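import numpy as np
import pandas as pd
import pytest

from mammotex import evaluate as ev
from mammotex import selection


def _separable(n=60, n_noise=4, gap=5.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    cols = {"signal": y * gap + rng.normal(0, 0.5, n)}
    for j in range(n_noise):
        cols[f"noise_{j}"] = rng.normal(size=n)
    return pd.DataFrame(cols), y


class TestTrainForest:
    def test_separable_training_accuracy_100(self):
        X, y = _separable()
        model = ev.train_forest(X.to_numpy(), y, ev.ForestParams(seed=0))
        assert (model.predict(X.to_numpy()) == y).mean() == 1.0

    def test_single_class_rejected(self):
        X, _ = _separable()
        with pytest.raises(ValueError):
            ev.train_forest(X.to_numpy(), np.zeros(len(X)), ev.ForestParams())

    def test_scores_are_vote_fractions_in_unit_interval(self):
        X, y = _separable(seed=1)
        model = ev.train_forest(X.to_numpy(), y, ev.ForestParams(n_trees=10, seed=0))
        scores = ev.predict_proba(model, X.to_numpy())
        # fully-grown trees vote 0/1, so scores are multiples of 1/n_trees
        assert np.allclose(scores * 10, np.round(scores * 10))

    def test_duplicated_training_rows_same_decisions(self):
        X, y = _separable(seed=2)
        test_X, _ = _separable(seed=3)
        a = ev.train_forest(X.to_numpy(), y, ev.ForestParams(seed=5))
        b = ev.train_forest(
            np.vstack([X.to_numpy()] * 2), np.concatenate([y, y]), ev.ForestParams(seed=5)
        )
        assert np.array_equal(a.predict(test_X.to_numpy()), b.predict(test_X.to_numpy()))

    def test_ensemble_beats_single_tree_on_noisy_data(self):
        deltas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 120
            y = np.repeat([0, 1], n // 2)
            X = rng.normal(0, 1, (n, 8)) + y[:, None] * 0.6
            perm = rng.permutation(n)
            X, y = X[perm], y[perm]
            train, test = slice(0, 80), slice(80, None)
            accs = []
            for n_trees in (1, 100):
                model = ev.train_forest(X[train], y[train], ev.ForestParams(n_trees, seed=seed))
                accs.append((model.predict(X[test]) == y[test]).mean())
            deltas.append(accs[1] - accs[0])
        assert np.mean(deltas) >= 0


class TestBinaryMetrics:
    def test_perfect_scores(self):
        m = ev.binary_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert (m.auc, m.accuracy, m.sensitivity, m.specificity) == (100, 100, 100, 100)

    def test_all_tied_scores_auc_50(self):
        assert ev.binary_metrics([1, 0, 1, 0], [0.3] * 4).auc == 50.0

    def test_worked_example(self):
        """y=(1,1,0,0), s=(0.9,0.4,0.6,0.1): 3 of 4 positive-negative pairs
        correctly ordered -> AUC 75; at threshold 0.5 one error each way."""
        m = ev.binary_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert m.auc == 75.0
        assert m.accuracy == 50.0 and m.sensitivity == 50.0 and m.specificity == 50.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            ev.binary_metrics([1, 1], [0.2, 0.4])


class TestRepeatedCV:
    def test_separable_high_auc_and_determinism(self):
        X, y = _separable(n=80, seed=4)
        kwargs = dict(method="embedded", k_features=2, rounds=2, folds=5, seed=7,
                      forest_params=ev.ForestParams(n_trees=25))
        a = ev.repeated_cv(X, y, **kwargs)
        b = ev.repeated_cv(X, y, **kwargs)
        assert a.per_round.equals(b.per_round)
        assert a.per_round["auc"].median() >= 95
        assert len(a.rankings) == 2 * 5

    def test_metrics_consistent_with_confusion_counts(self):
        X, y = _separable(n=40, seed=5)
        rep = ev.repeated_cv(X, y, "filter", 1, rounds=1, folds=4, seed=0,
                             forest_params=ev.ForestParams(n_trees=10))
        row = rep.per_round.iloc[0]
        n_pos = n_neg = 20
        acc = (row.sensitivity / 100 * n_pos + row.specificity / 100 * n_neg) / 40 * 100
        assert row.accuracy == pytest.approx(acc)

    def test_infeasible_stratification_rejected(self):
        X, y = _separable(n=12)
        with pytest.raises(ValueError, match="per class"):
            ev.repeated_cv(X, y, "filter", 1, rounds=1, folds=10, seed=0)

    def test_k_features_out_of_range_rejected(self):
        X, y = _separable()
        with pytest.raises(ValueError):
            ev.repeated_cv(X, y, "filter", 99, rounds=1, folds=5, seed=0)

    def test_no_leakage_fold_level(self):
        """Selection and training depend only on the training fold: corrupting
        held-out rows changes neither the ranking nor the trained model."""
        X, y = _separable(n=60, seed=6)
        train_idx = np.arange(40)
        test_idx = np.arange(40, 60)
        ranking = selection.embedded_rank(X.iloc[train_idx], y[train_idx], seed=3)
        corrupted = X.copy()
        corrupted.iloc[test_idx] = 1e6
        ranking_c = selection.embedded_rank(corrupted.iloc[train_idx], y[train_idx], seed=3)
        assert ranking.features == ranking_c.features

        cols = ranking.top(2)
        m1 = ev.train_forest(X.iloc[train_idx][cols].to_numpy(), y[train_idx],
                             ev.ForestParams(seed=9))
        m2 = ev.train_forest(corrupted.iloc[train_idx][cols].to_numpy(), y[train_idx],
                             ev.ForestParams(seed=9))
        probe = X.iloc[test_idx][cols].to_numpy()
        assert np.array_equal(ev.predict_proba(m1, probe), ev.predict_proba(m2, probe))


class TestFeatureCountSweep:
    def test_full_k_matches_plain_cv_exactly(self):
        X, y = _separable(n=40, n_noise=3, seed=7)
        fp = ev.ForestParams(n_trees=10)
        sweep = ev.feature_count_sweep(X, y, "filter", k_grid=[X.shape[1]],
                                       rounds=1, folds=4, seed=3, forest_params=fp)
        plain = ev.repeated_cv(X, y, "filter", X.shape[1], rounds=1, folds=4,
                               seed=3, forest_params=fp)
        assert sweep.reports[X.shape[1]].per_round.equals(plain.per_round)

    def test_two_informative_features_need_both(self):
        """Labels depend on the sum of two features; k=1 must underperform the
        argmax-k accuracy on average over seeds."""
        fp = ev.ForestParams(n_trees=25)
        gaps = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            n = 120
            f1, f2 = rng.normal(size=(2, n))
            y = (f1 + f2 > 0).astype(int)
            X = pd.DataFrame({"f1": f1, "f2": f2,
                              **{f"n{j}": rng.normal(size=n) for j in range(4)}})
            if min(np.bincount(y)) < 5:
                continue
            sweep = ev.feature_count_sweep(X, y, "embedded", k_grid=[1, 2],
                                           rounds=1, folds=5, seed=seed,
                                           forest_params=fp)
            gaps.append(sweep.median_accuracy[2] - sweep.median_accuracy[1])
        assert np.mean(gaps) > 0
        assert len(gaps) >= 5

    def test_sweep_reproducible(self):
        X, y = _separable(n=40, seed=8)
        fp = ev.ForestParams(n_trees=10)
        runs = [
            ev.feature_count_sweep(X, y, "embedded", k_grid=[1, 3], rounds=1,
                                   folds=4, seed=5, forest_params=fp).median_accuracy
            for _ in range(2)
        ]
        assert runs[0] == runs[1]


class TestCompareMethods:
    def _report(self, values):
        per_round = pd.DataFrame({m: values for m in ev.METRICS})
        return ev.CVReport("filter", 2, len(values), 10, 0, per_round)

    def test_identical_reports_p_one(self):
        a = self._report(np.linspace(80, 95, 20))
        assert all(p == 1.0 for p in ev.compare_methods(a, a).values())

    def test_shifted_report_significant(self):
        base = np.linspace(80, 90, 100)
        p = ev.compare_methods(self._report(base), self._report(base + 5), 4)
        assert all(v < 0.01 for v in p.values())

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(0)
        a = self._report(rng.normal(85, 2, 30))
        b = self._report(rng.normal(85, 2, 30))
        assert all(v <= 1.0 for v in ev.compare_methods(a, b, 8).values())

    def test_mismatched_rounds_rejected(self):
        with pytest.raises(ValueError):
            ev.compare_methods(self._report(np.ones(5)), self._report(np.ones(6)))
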