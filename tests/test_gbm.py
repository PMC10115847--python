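"""Gene-disjoint folds, feature screening, and the ternary-tree booster."""

import numpy as np
import pytest

from epivep.gbm import (
    GbmConfig,
    GradientBoostingModel,
    GradientBoostingResults,
    best_split,
    default_tuning_grid,
    fit_tree,
    make_gene_folds,
    predict_scores,
    screen_features,
    tree_predict,
    tune_hyperparameters,
)
from epivep.synthetic import SyntheticSpec, synth_feature_table


@pytest.fixture(scope="module")
def signal_table():
    """400 variants over 40 genes, two 2-SD features, 10% missing cells."""
    spec = SyntheticSpec(seed=21)
    rng = np.random.default_rng(8)
    y = (rng.random(400) < 0.6).astype(int)
    table, _ = synth_feature_table(y, spec)
    return table, y


class TestGeneFolds:
    def test_two_genes_two_folds(self):
        genes = ["A"] * 5 + ["B"] * 5
        labels = [1, 0, 1, 0, 1] * 2
        folds = make_gene_folds(genes, labels, k=2, seed=0)
        assert set(folds.gene_to_fold.values()) == {0, 1}

    def test_no_gene_spans_folds(self, signal_table):
        table, y = signal_table
        folds = make_gene_folds(table.genes(), y, k=4, seed=0)
        ids = folds.variant_folds(table.genes())
        for gene in set(table.genes()):
            assert len(set(ids[table.genes() == gene])) == 1

    def test_forty_gene_fixture_class_balance(self, signal_table):
        table, y = signal_table
        folds = make_gene_folds(table.genes(), y, k=4, seed=0)
        report = folds.report(table.genes(), y)
        assert (report["deviation"].abs() <= 0.05).all()

    def test_k_exceeding_genes_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_gene_folds(["A", "A", "B"], [0, 1, 0], k=3)


class TestScreen:
    def test_rule_application(self, signal_table):
        table, y = signal_table
        results = {s.feature: s for s in screen_features(table, y, k=5)}
        # the two planted 2-SD features must pass, pure-noise ones must not
        assert results["psic_diff"].kept and results["evmutation"].kept
        assert not results["phylop"].kept

    def test_perfectly_separating_feature(self):
        spec = SyntheticSpec(seed=22, missing_rate=0.0,
                             effect_sizes={"psic_diff": 40.0})
        rng = np.random.default_rng(9)
        y = (rng.random(200) < 0.5).astype(int)
        table, _ = synth_feature_table(y, spec)
        screen = {s.feature: s for s in screen_features(table, y, k=5)}
        assert screen["psic_diff"].kept
        assert screen["psic_diff"].auc >= 0.99

    def test_all_missing_feature_dropped_with_reason(self, signal_table):
        table, y = signal_table
        broken = table.subset(np.ones(len(table), dtype=bool))
        broken.data["evmutation"] = np.nan
        screen = {s.feature: s for s in screen_features(broken, y, k=5)}
        assert not screen["evmutation"].kept
        assert screen["evmutation"].reason == "all values missing"


class TestTreeFitting:
    def test_depth1_equals_exhaustive_stump_oracle(self, oracles):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n, p = int(rng.integers(10, 40)), int(rng.integers(2, 5))
            X = rng.standard_normal((n, p))
            r = rng.standard_normal(n)
            w = np.full(n, 0.25)
            tree = fit_tree(X, r, w, n_splits=1)
            want = oracles.stump(X, r)
            assert tree["feature"] == want[1]
            assert tree["threshold"] == pytest.approx(want[2])

    def test_missing_rows_routed_to_missing_child(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0], [np.nan], [np.nan]])
        r = np.array([-1.0, -1.0, 1.0, 1.0, 5.0, 5.0])
        w = np.full(6, 0.25)
        tree = fit_tree(X, r, w, n_splits=1)
        pred = tree_predict(tree, X)
        assert pred[4] == pred[5]
        # missing rows share the dedicated node value: sum(r)/sum(w) = 10/0.5
        assert pred[4] == pytest.approx(10.0 / 0.5, rel=1e-6)

    def test_empty_missing_child_inherits_node_value(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        r = np.array([-1.0, -1.0, 1.0, 1.0])
        tree = fit_tree(X, r, np.full(4, 0.25), n_splits=1)
        out = tree_predict(tree, np.array([[np.nan]]))
        assert out[0] == pytest.approx(np.sum(r) / 1.0, abs=1e-6)


class TestBoosting:
    def test_constant_features_predict_base_rate(self):
        X = np.ones((20, 3))
        y = np.array([1] * 12 + [0] * 8)
        res = GradientBoostingModel(X, y, GbmConfig(n_trees=20)).fit()
        assert np.allclose(res.predict_proba(X), 0.6, atol=1e-9)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single-class"):
            GradientBoostingModel(np.zeros((5, 2)), [1] * 5, GbmConfig())

    def test_training_deviance_nonincreasing(self, signal_table):
        table, y = signal_table
        res = GradientBoostingModel(table, y,
                                    GbmConfig(shrinkage=0.01, n_trees=60)).fit()
        assert np.all(np.diff(res.train_deviance) <= 1e-12)

    def test_separable_data_training_accuracy_approaches_one(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((120, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        res = GradientBoostingModel(
            X, y, GbmConfig(shrinkage=0.3, interaction_depth=2, n_trees=200)).fit()
        assert (res.predict_class(X) == y).mean() >= 0.99

    def test_row_permutation_invariance(self, signal_table):
        table, y = signal_table
        X = table.matrix()
        cfg = GbmConfig(shrinkage=0.05, n_trees=15)
        res_a = GradientBoostingModel(X, y, cfg).fit()
        perm = np.random.default_rng(13).permutation(len(y))
        res_b = GradientBoostingModel(X[perm], y[perm], cfg).fit()
        assert np.allclose(res_a.predict_proba(X), res_b.predict_proba(X), atol=1e-10)

    def test_all_missing_row_scored_finite(self, signal_table):
        table, y = signal_table
        res = GradientBoostingModel(table, y, GbmConfig(n_trees=25)).fit()
        ghost = np.full((1, len(table.feature_names)), np.nan)
        p = res.predict_proba(ghost)
        assert np.isfinite(p).all() and 0 <= p[0] <= 1

    def test_threshold_is_strict(self):
        res = GradientBoostingResults(
            model=None, trees=[], f0=0.0, train_deviance=np.array([1.0]),
            config=GbmConfig(), feature_names=["a"])
        # empty ensemble, f0=0 -> probability exactly 0.5 -> benign
        assert res.predict_class(np.array([[1.0]]))[0] == 0

    def test_json_roundtrip_preserves_predictions(self, signal_table):
        table, y = signal_table
        res = GradientBoostingModel(table, y, GbmConfig(n_trees=10)).fit()
        back = GradientBoostingResults.from_json(res.to_json())
        assert np.allclose(back.predict_proba(table), res.predict_proba(table))
        assert back.summary() == res.summary()

    def test_predict_scores_frame(self, signal_table):
        table, y = signal_table
        res = GradientBoostingModel(table, y, GbmConfig(n_trees=10)).fit()
        out = predict_scores(res, table)
        assert set(out["class"]) <= {"pathogenic", "benign"}
        assert ((out["probability"] > 0.5) == (out["class"] == "pathogenic")).all()


class TestTuning:
    def test_default_grid_is_nine_points(self):
        grid = default_tuning_grid()
        assert len(grid) == 9
        assert sorted({c.shrinkage for c in grid}) == [0.001, 0.0055, 0.01]
        assert sorted({c.interaction_depth for c in grid}) == [1, 2, 3]

    def test_selection_rule(self, signal_table):
        table, y = signal_table
        folds = make_gene_folds(table.genes(), y, k=4, seed=0)
        grid = [GbmConfig(shrinkage=0.1, interaction_depth=d, n_trees=30)
                for d in (1, 2)]
        best, report = tune_hyperparameters(table, y, folds, grid)
        assert len(report) == 2
        winner = report.sort_values(["gap", "balance_sum"],
                                    ascending=[True, False]).iloc[0]
        assert best.interaction_depth == int(winner["interaction_depth"])

    def test_empty_grid_errors(self, signal_table):
        table, y = signal_table
        folds = make_gene_folds(table.genes(), y, k=4, seed=0)
        with pytest.raises(ValueError, match="empty"):
            tune_hyperparameters(table, y, folds, [])
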