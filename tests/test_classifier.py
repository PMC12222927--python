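import numpy as np
import pandas as pd
import pytest

from lncspect import (
    FeatureTable,
    ModelBundle,
    cross_validate,
    evaluate,
    generate_feature_toy,
    pca_explore,
    predict,
    train,
    tune_hyperparameters,
)
from lncspect.classifier import mann_whitney_auc

#: Small hyperparameters for fast test-time training.
FAST_HP = {"iterations": 60, "depth": 4, "learning_rate": 0.2}


def separable_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    ids = pd.Index([f"s{i}" for i in range(n)], name="id")
    x0 = np.concatenate([rng.normal(-3, 0.5, half), rng.normal(3, 0.5, half)])
    x1 = rng.normal(size=n)
    y = pd.Series(["mRNA"] * half + ["lncRNA"] * half, index=ids)
    return FeatureTable(pd.DataFrame({"f0": x0, "f1": x1}, index=ids), y)


class TestTrainPredict:
    def test_separable_training_accuracy_is_one(self):
        t = separable_table()
        bundle = train(t, hyperparams=FAST_HP, seed=0)
        rep = evaluate(predict(bundle, t), t.y)
        assert rep.accuracy == 100.0

    def test_column_order_normalized_but_mismatch_rejected(self):
        t = separable_table()
        bundle = train(t, hyperparams=FAST_HP)
        reordered = FeatureTable(t.X[["f1", "f0"]].copy(), t.y)
        p1 = predict(bundle, t)
        p2 = predict(bundle, reordered)
        np.testing.assert_array_equal(p1["probability"], p2["probability"])
        missing = FeatureTable(t.X[["f0"]].copy(), t.y)
        with pytest.raises(ValueError, match="f1"):
            predict(bundle, missing)

    def test_duplicated_row_gets_identical_probability(self):
        t = separable_table()
        bundle = train(t, hyperparams=FAST_HP)
        dup = FeatureTable(
            pd.concat([t.X.iloc[[0]], t.X.iloc[[0]].set_axis(["copy"], axis=0)])
        )
        p = predict(bundle, dup)
        assert p["probability"].iloc[0] == p["probability"].iloc[1]

    def test_threshold_boundary_inclusive_and_monotone(self):
        t = separable_table()
        bundle = train(t, hyperparams=FAST_HP)
        p = predict(bundle, t)
        # boundary convention: probability == threshold counts positive
        at = p["probability"] >= bundle.threshold
        assert ((p["label"] == "lncRNA") == at).all()
        counts = []
        for thr in (0.2, 0.5, 0.8):
            b = ModelBundle(bundle.backend, bundle.feature_names, bundle.booster, threshold=thr)
            counts.append(int((predict(b, t)["label"] == "lncRNA").sum()))
        assert counts == sorted(counts, reverse=True)

    def test_single_class_rejected(self):
        t = separable_table()
        t1 = FeatureTable(t.X.copy(), pd.Series("mRNA", index=t.X.index))
        with pytest.raises(ValueError):
            train(t1)

    def test_catboost_backend_reports_unavailable(self):
        with pytest.raises(RuntimeError, match="catboost"):
            train(separable_table(), backend="catboost")

    def test_bundle_roundtrip_bit_identical(self, tmp_path):
        t = separable_table()
        bundle = train(t, hyperparams=FAST_HP, seed=3)
        path = tmp_path / "model.lnb"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        np.testing.assert_array_equal(
            predict(bundle, t)["probability"].to_numpy(),
            predict(loaded, t)["probability"].to_numpy(),
        )
        assert loaded.feature_names == bundle.feature_names
        assert loaded.metadata["training_hash"] == bundle.metadata["training_hash"]


class TestCrossValidate:
    def test_same_seed_identical_report(self):
        t = separable_table(n=100, seed=1)
        a = cross_validate(t, hyperparams=FAST_HP, folds=5, seed=9)
        b = cross_validate(t, hyperparams=FAST_HP, folds=5, seed=9)
        assert a.to_dict() == b.to_dict()

    def test_stratified_fold_sizes(self):
        from sklearn.model_selection import StratifiedKFold

        t = separable_table(n=100)
        y01 = (t.y == "lncRNA").to_numpy(int)
        for _, test_idx in StratifiedKFold(10, shuffle=True, random_state=0).split(t.X, y01):
            assert len(test_idx) == 10
            assert y01[test_idx].sum() == 5

    def test_too_many_folds_rejected(self):
        t = separable_table(n=20)
        with pytest.raises(ValueError):
            cross_validate(t, folds=12)

    def test_permuted_labels_auc_is_chance(self):
        """Label permutation destroys signal: 5-fold CV AUC ~ 50%."""
        rng = np.random.default_rng(21)
        toy = generate_feature_toy(n=2000, n_noise_features=2, seed=21)
        permuted = pd.Series(
            rng.permutation(toy.y.to_numpy()), index=toy.y.index, name="class"
        )
        t = FeatureTable(toy.X.copy(), permuted)
        rep = cross_validate(t, hyperparams=FAST_HP, folds=5, seed=21)
        assert abs(rep.auc - 50.0) <= 5.0


class TestEvaluate:
    @staticmethod
    def _preds(tp=98, fn=2, tn=95, fp=5, seed=0):
        rng = np.random.default_rng(seed)
        rows, truth = [], {}
        i = 0
        for count, label, cls in (
            (tp, "lncRNA", "lncRNA"),
            (fn, "mRNA", "lncRNA"),
            (tn, "mRNA", "mRNA"),
            (fp, "lncRNA", "mRNA"),
        ):
            for _ in range(count):
                prob = rng.uniform(0.5, 1.0) if label == "lncRNA" else rng.uniform(0.0, 0.5)
                rows.append((f"s{i}", prob, label))
                truth[f"s{i}"] = cls
                i += 1
        df = pd.DataFrame(rows, columns=["id", "probability", "label"]).set_index("id")
        return df, truth

    def test_confusion_arithmetic(self):
        preds, truth = self._preds()
        rep = evaluate(preds, truth)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (98, 2, 95, 5)
        assert rep.sensitivity == pytest.approx(98.0)
        assert rep.specificity == pytest.approx(95.0)
        assert rep.accuracy == pytest.approx(96.5)
        assert rep.precision == pytest.approx(100 * 98 / 103)

    def test_metric_identities_always_hold(self):
        for seed in range(5):
            preds, truth = self._preds(
                tp=30 + seed, fn=10, tn=40, fp=7 + seed, seed=seed
            )
            r = evaluate(preds, truth)
            n = r.tp + r.tn + r.fp + r.fn
            assert r.accuracy == pytest.approx(100 * (r.tp + r.tn) / n)
            if r.precision + r.sensitivity > 0:
                assert r.f1 == pytest.approx(
                    2 * r.precision * r.sensitivity / (r.precision + r.sensitivity)
                )
            fprs, tprs = zip(*r.roc)
            assert (fprs[0], tprs[0]) == (0.0, 0.0)
            assert (fprs[-1], tprs[-1]) == (1.0, 1.0)
            assert all(a <= b for a, b in zip(tprs, tprs[1:]))

    def test_perfect_ranking_auc_100(self):
        preds, truth = self._preds(tp=50, fn=0, tn=50, fp=0)
        assert evaluate(preds, truth).auc == pytest.approx(100.0)

    def test_auc_equals_pairwise_oracle(self):
        rng = np.random.default_rng(17)
        scores = rng.random(500)
        scores[::7] = scores[::2][: len(scores[::7])]  # inject ties
        y = rng.integers(0, 2, 500)
        y[0], y[1] = 0, 1
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        assert mann_whitney_auc(scores, y) == pytest.approx(oracle)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        a = mann_whitney_auc(scores, y)
        b = mann_whitney_auc(np.exp(5 * scores), y)
        assert a == pytest.approx(b)

    def test_unknown_ids_and_empty_truth_rejected(self):
        preds, truth = self._preds(tp=2, fn=1, tn=2, fp=1)
        with pytest.raises(ValueError):
            evaluate(preds, {})
        truth.pop("s0")
        with pytest.raises(ValueError):
            evaluate(preds, truth)


class TestTuning:
    def test_budget_one_returns_a_configuration(self):
        t = separable_table(n=100)
        hp = tune_hyperparameters(t, budget=1, seed=0, folds=3)
        assert set(hp) >= {"depth", "iterations", "learning_rate", "l2_regularization"}

    def test_best_auc_nondecreasing_in_budget(self):
        t = separable_table(n=100, seed=5)
        a1 = tune_hyperparameters(t, budget=1, seed=4, folds=3)["cv_auc"]
        a3 = tune_hyperparameters(t, budget=3, seed=4, folds=3)["cv_auc"]
        assert a3 >= a1

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters(separable_table(), budget=0)


class TestPcaExplore:
    def test_correlated_columns_load_on_pc1(self):
        rng = np.random.default_rng(0)
        ids = pd.Index([f"s{i}" for i in range(50)], name="id")
        x = rng.normal(size=50)
        t = FeatureTable(pd.DataFrame({"a": x, "b": 2 * x + 1}, index=ids))
        frac, coords = pca_explore(t)
        assert frac[0] == pytest.approx(1.0)
        assert coords.shape == (50, 2)

    def test_fractions_sum_to_one_and_symmetry(self):
        rng = np.random.default_rng(1)
        ids = pd.Index([f"s{i}" for i in range(3000)], name="id")
        X = pd.DataFrame(rng.normal(size=(3000, 4)), index=ids, columns=list("abcd"))
        frac, _ = pca_explore(FeatureTable(X))
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(frac, 0.25, atol=0.03)  # independent equal-variance columns

    def test_degenerate_table_rejected(self):
        ids = pd.Index(["a", "b", "c"], name="id")
        t = FeatureTable(pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [2.0, 2.0, 2.0]}, index=ids))
        with pytest.raises(ValueError):
            pca_explore(t)
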