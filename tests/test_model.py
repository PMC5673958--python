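"""Model layer: splitting, repeated CV, grid search, training,
prediction, classification metrics, threshold choice and importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import g4boost as g
from g4boost.model import DEFAULT_THRESHOLD, _split_xy


def toy_dataset(n=120, seed=0, noise=0.5):
    """Learnable regression problem: mm is linear in two features plus
    noise; extra feature is irrelevant."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    x3 = rng.normal(size=n)
    mm = 20 + 8 * x1 - 5 * x2 + rng.normal(0, noise, size=n)
    return pd.DataFrame({"f1": x1, "f2": x2, "f3": x3, "mm": mm})


class TestSplit:
    def test_sizes_70_30(self):
        tr, te = g.split_train_test(toy_dataset(10), 0.7, seed=1)
        assert len(tr) == 7 and len(te) == 3

    def test_same_seed_same_split(self):
        ds = toy_dataset(50)
        tr1, _ = g.split_train_test(ds, 0.7, seed=5)
        tr2, _ = g.split_train_test(ds, 0.7, seed=5)
        assert tr1.index.equals(tr2.index)

    def test_partition_is_disjoint_and_exhaustive(self):
        ds = toy_dataset(37)
        tr, te = g.split_train_test(ds, 0.7, seed=2)
        union = pd.concat([tr, te]).sort_index()
        assert union.equals(ds.sort_index())
        assert set(tr.index).isdisjoint(te.index)


class TestRepeatedCV:
    def test_two_by_three_design_gives_six_rounds(self):
        cv = g.repeated_cv(toy_dataset(60), g.small_grid()[0], seed=3)
        assert len(cv.rmses) == 6
        assert cv.mean_rmse == pytest.approx(np.mean(cv.rmses))

    def test_deterministic_under_fixed_seed(self):
        ds = toy_dataset(60)
        a = g.repeated_cv(ds, g.small_grid()[0], seed=7)
        b = g.repeated_cv(ds, g.small_grid()[0], seed=7)
        assert a.rmses == b.rmses

    def test_invariant_to_row_order_given_seed(self):
        ds = toy_dataset(60)
        shuffled = ds.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = g.repeated_cv(ds, g.small_grid()[0], seed=7)
        b = g.repeated_cv(shuffled, g.small_grid()[0], seed=7)
        assert a.mean_rmse == pytest.approx(b.mean_rmse, rel=0.25)

    def test_constant_target_gives_near_zero_rmse(self):
        ds = toy_dataset(30)
        ds["mm"] = 7.0
        cv = g.repeated_cv(ds, g.small_grid()[0], seed=1)
        assert cv.mean_rmse == pytest.approx(0.0, abs=1e-3)

    def test_learnable_target_beats_target_sd(self):
        ds = toy_dataset(300, noise=0.5)
        cv = g.repeated_cv(ds, g.GBMConfig(300, 3, 2.0, 0.1, 0.8), seed=4)
        assert cv.mean_rmse < 0.3 * ds["mm"].std()

    def test_fewer_rows_than_folds_rejected(self):
        with pytest.raises(ValueError):
            g.repeated_cv(toy_dataset(2), g.small_grid()[0], folds=3)


class TestGridSearch:
    def test_singleton_grid_returned(self):
        cfg = g.small_grid()[0]
        ranked, best = g.grid_search(toy_dataset(60), [cfg], seed=1)
        assert best == cfg and len(ranked) == 1

    def test_sane_config_beats_over_regularized(self):
        ds = toy_dataset(200, noise=0.5)
        over = g.GBMConfig(10, 1, 1e6, 0.1, 0.6)  # constant-ish model
        sane = g.GBMConfig(300, 3, 2.0, 0.1, 0.8)
        ranked, best = g.grid_search(ds, [over, sane], seed=2)
        assert best == sane
        assert ranked[0].config == sane

    def test_results_serializable(self):
        ranked, _ = g.grid_search(toy_dataset(60), g.small_grid()[:2], seed=1)
        report = g.cv_report(ranked)
        assert {"n_trees", "mean_rmse"} <= set(report.columns)
        assert report["mean_rmse"].is_monotonic_increasing

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            g.grid_search(toy_dataset(30), [])


class TestConfigValidation:
    def test_paper_optimum_is_the_default(self):
        cfg = g.GBMConfig()
        assert (
            cfg.n_trees, cfg.interaction_depth, cfg.min_child_weight,
            cfg.learning_rate, cfg.bag_fraction,
        ) == (2500, 14, 65.0, 0.01, 0.6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_trees": 0},
            {"interaction_depth": 0},
            {"min_child_weight": -1},
            {"learning_rate": 0.0},
            {"learning_rate": 1.5},
            {"bag_fraction": 0.0},
        ],
    )
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            g.GBMConfig(**kwargs)


class TestTrainPredict:
    def test_constant_target_predicts_constant(self):
        ds = toy_dataset(40)
        ds["mm"] = 13.0
        model = g.train_final(ds, g.small_grid()[0], seed=1)
        X, _ = _split_xy(ds)
        assert np.allclose(g.predict(model, X), 13.0, atol=1e-3)

    def test_default_threshold_without_data_is_19_1(self):
        ds = toy_dataset(40)
        model = g.train_final(ds, g.small_grid()[0], seed=1)
        assert model.threshold == DEFAULT_THRESHOLD == 19.1

    def test_reload_from_disk_identical_predictions(self, tmp_path):
        ds = toy_dataset(80)
        model = g.train_final(ds, g.small_grid()[0], seed=1)
        model.save(tmp_path / "bundle")
        loaded = g.TrainedModel.load(tmp_path / "bundle")
        X, _ = _split_xy(ds)
        assert np.allclose(g.predict(model, X), g.predict(loaded, X))
        assert loaded.threshold == model.threshold
        assert loaded.config == model.config

    def test_training_fit_beats_internal_cv(self):
        ds = toy_dataset(150)
        cfg = g.GBMConfig(300, 3, 2.0, 0.1, 0.8)
        cv = g.repeated_cv(ds, cfg, seed=2)
        model = g.train_final(ds, cfg, seed=2)
        X, y = _split_xy(ds)
        fit_rmse = float(np.sqrt(np.mean((g.predict(model, X) - y) ** 2)))
        assert fit_rmse <= cv.mean_rmse

    def test_permuting_rows_permutes_scores(self):
        ds = toy_dataset(60)
        model = g.train_final(ds, g.small_grid()[0], seed=1)
        X, _ = _split_xy(ds)
        perm = np.random.default_rng(3).permutation(len(X))
        assert np.allclose(
            g.predict(model, X.iloc[perm]), g.predict(model, X)[perm]
        )

    def test_missing_feature_named_in_error(self):
        ds = toy_dataset(40)
        model = g.train_final(ds, g.small_grid()[0], seed=1)
        with pytest.raises(KeyError, match="f2"):
            g.predict(model, _split_xy(ds)[0].drop(columns=["f2"]))


class TestConfusionMetrics:
    @staticmethod
    def _from_counts(tp, fn, tn, fp):
        t = np.array([True] * (tp + fn) + [False] * (tn + fp))
        p = np.array(
            [True] * tp + [False] * fn + [False] * tn + [True] * fp
        )
        return g.confusion_metrics(t, p)

    def test_balanced_example(self):
        m = self._from_counts(tp=80, fn=20, tn=80, fp=20)
        assert m.as_percent() == {"TPR": 80.0, "TNR": 80.0, "FPR": 20.0, "FDR": 20.0}

    def test_all_correct(self):
        m = self._from_counts(tp=10, fn=0, tn=10, fp=0)
        assert m.tpr == 1.0 and m.fpr == 0.0

    def test_fdr_differs_from_fpr_when_unbalanced(self):
        m = self._from_counts(tp=842, fn=158, tn=400, fp=100)
        assert m.fdr == pytest.approx(100 / 942)
        assert m.fpr == pytest.approx(0.2)
        assert m.fdr != m.fpr

    def test_empty_class_flagged_not_nan(self):
        m = g.confusion_metrics(np.array([True, True]), np.array([True, False]))
        assert m.tnr is None and m.fpr is None
        assert m.tpr == 0.5

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        tn=st.integers(0, 50), fp=st.integers(0, 50),
    )
    def test_rate_identities_on_fuzzed_tables(self, tp, fn, tn, fp):
        m = self._from_counts(tp, fn, tn, fp)
        if tp + fn:
            fnr = fn / (tp + fn)
            assert m.tpr + fnr == pytest.approx(1.0)
        if tn + fp:
            assert m.tnr + m.fpr == pytest.approx(1.0)


class TestChooseThreshold:
    def test_bimodal_toy_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        mm = np.concatenate([rng.normal(8, 1, 200), rng.normal(40, 1, 200)])
        scores = mm + rng.normal(0, 0.5, 400)
        t = g.choose_threshold(scores, mm, candidates=np.arange(2.0, 60.0, 0.5))
        assert 10 < t < 38

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        mm = rng.uniform(0, 50, 300)
        scores = mm + rng.normal(0, 6, 300)
        cands = np.arange(5.0, 45.0, 1.0)
        t = g.choose_threshold(scores, mm, candidates=cands)
        # naive scan: evaluate every candidate from scratch
        def objective(c):
            truth, pred = mm >= c, scores >= c
            tp = np.sum(truth & pred); fn = np.sum(truth & ~pred)
            tn = np.sum(~truth & ~pred); fp = np.sum(~truth & pred)
            return min(tp / (tp + fn), tn / (tn + fp))
        objs = [objective(c) for c in cands]
        best = cands[int(np.argmax(objs))]  # argmax takes first -> lowest tie
        assert t == best

    def test_one_class_truth_raises(self):
        with pytest.raises(ValueError):
            g.choose_threshold(
                np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                candidates=np.array([50.0]),
            )


@pytest.fixture(scope="module")
def trained():
    ds = toy_dataset(300, noise=0.5)
    model = g.train_final(ds, g.GBMConfig(300, 3, 2.0, 0.1, 0.8), seed=5)
    return model, ds


class TestImportance:
    def test_top_feature_normalized_to_one(self, trained):
        model, ds = trained
        rep = g.importance_report(model, ds)
        assert rep.iloc[0]["importance"] == 1.0
        assert ((rep["importance"] >= 0) & (rep["importance"] <= 1)).all()

    def test_irrelevant_feature_near_zero_importance(self, trained):
        model, ds = trained
        rep = g.importance_report(model, ds).set_index("feature")
        assert rep.loc["f3", "importance"] < 0.05

    def test_monotone_positive_feature_marked_plus(self, trained):
        model, ds = trained
        rep = g.importance_report(model, ds).set_index("feature")
        assert rep.loc["f1", "direction"] == "+"
        assert rep.loc["f2", "direction"] == "-"

    def test_never_split_feature_has_zero_importance(self):
        ds = toy_dataset(100)
        ds["constant"] = 1.0
        model = g.train_final(ds, g.small_grid()[0], seed=2)
        rep = g.importance_report(model, ds).set_index("feature")
        assert rep.loc["constant", "importance"] == 0.0
        assert rep.loc["constant", "direction"] == "*"
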