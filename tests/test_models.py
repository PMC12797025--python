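import logging

import numpy as np
import pytest

from fibrilscreen.chem import FeatureMatrix
from fibrilscreen.labeling import BINDER, NON_BINDER
from fibrilscreen.models import (
    ModelFamily,
    SelectionConfig,
    classification_report,
    cross_validate,
    default_families,
    f1_score_from_pr,
    select_features,
    tune_and_train,
)


# ---------------------------------------------------------------------------
# classification_report vs a hand-built confusion-matrix oracle
# ---------------------------------------------------------------------------

def _report_oracle(y_true, y_pred):
    """Independent confusion-matrix arithmetic, one class at a time."""
    out = {}
    for cls in (BINDER, NON_BINDER):
        tp = sum(t == cls and p == cls for t, p in zip(y_true, y_pred))
        fp = sum(t != cls and p == cls for t, p in zip(y_true, y_pred))
        fn = sum(t == cls and p != cls for t, p in zip(y_true, y_pred))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[cls] = (prec, rec, f1, tp + fn)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
    n = len(y_true)
    macro = tuple(
        sum(out[c][k] for c in out) / 2 for k in range(3)
    )
    weighted = tuple(
        sum(out[c][k] * out[c][3] / n for c in out) for k in range(3)
    )
    return out, acc, macro, weighted


def _random_labels(rng, n):
    labels = [BINDER, NON_BINDER]
    y_true = [labels[i] for i in rng.integers(0, 2, n)]
    y_pred = [labels[i] for i in rng.integers(0, 2, n)]
    return y_true, y_pred


class TestClassificationReport:
    def test_oracle_agreement_1000_random_sets(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            y_true, y_pred = _random_labels(rng, int(rng.integers(2, 40)))
            rep = classification_report(y_true, y_pred)
            per_class, acc, macro, weighted = _report_oracle(y_true, y_pred)
            for cls in (BINDER, NON_BINDER):
                m = rep.per_class[cls]
                assert (m.precision, m.recall, m.f1, m.support) == per_class[cls]
            assert rep.accuracy == acc
            assert (rep.macro_precision, rep.macro_recall, rep.macro_f1) == macro
            assert (
                rep.weighted_precision,
                rep.weighted_recall,
                rep.weighted_f1,
            ) == pytest.approx(weighted)

    def test_published_binder_row_f1(self):
        # precision 0.47, recall 0.89 -> F1 rounds to 0.62
        assert round(f1_score_from_pr(0.47, 0.89), 2) == 0.62

    def test_perfect_predictions(self):
        y = [BINDER, NON_BINDER, BINDER]
        rep = classification_report(y, y)
        assert rep.accuracy == 1.0
        assert rep.macro_f1 == 1.0
        assert rep.weighted_f1 == 1.0

    def test_prospective_confusion_counts(self):
        # TP=7 FP=6 FN=2 TN=15: expected metrics derived by brute-force
        # confusion arithmetic (binder P=7/13, R=7/9; non-binder P=15/17,
        # R=15/21), frozen here at 2 dp
        y_true = [BINDER] * 7 + [NON_BINDER] * 6 + [BINDER] * 2 + [NON_BINDER] * 15
        y_pred = [BINDER] * 7 + [BINDER] * 6 + [NON_BINDER] * 2 + [NON_BINDER] * 15
        rep = classification_report(y_true, y_pred)
        assert round(rep.per_class[NON_BINDER].f1, 2) == 0.79
        assert round(rep.macro_f1, 2) == 0.71
        assert round(rep.weighted_f1, 2) == 0.74

    def test_zero_predicted_positives_flagged(self):
        rep = classification_report([BINDER, NON_BINDER], [NON_BINDER, NON_BINDER])
        assert rep.per_class[BINDER].precision == 0.0
        assert f"{BINDER}:precision" in rep.zero_division_flags

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            classification_report([], [])

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError):
            classification_report([BINDER], ["maybe"])

    def test_macro_f1_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        y_true, y_pred = _random_labels(rng, 30)
        swap = {BINDER: NON_BINDER, NON_BINDER: BINDER}
        a = classification_report(y_true, y_pred)
        b = classification_report([swap[t] for t in y_true], [swap[p] for p in y_pred])
        assert a.macro_f1 == pytest.approx(b.macro_f1)
        assert a.accuracy == pytest.approx(b.accuracy)

    def test_text_layout(self):
        rep = classification_report([BINDER, NON_BINDER], [BINDER, NON_BINDER])
        text = rep.to_text()
        for row in ("Non-binder", "Binder", "Accuracy", "Macro", "Weighted"):
            assert row in text


# ---------------------------------------------------------------------------
# cross-validation engine
# ---------------------------------------------------------------------------

def _separable_matrix(n=120, n_noise=10, seed=0):
    """Feature 0 separates classes exactly; the rest is noise."""
    rng = np.random.default_rng(seed)
    y = np.array([BINDER] * (n // 3) + [NON_BINDER] * (n - n // 3))
    signal = np.where(y == BINDER, 1.0, -1.0) + rng.normal(0, 0.05, n)
    X = np.column_stack([signal] + [rng.normal(size=n) for _ in range(n_noise)])
    matrix = FeatureMatrix(
        ids=[f"s{i}" for i in range(n)],
        X=X,
        feature_ids=[f"desc:f{j}" for j in range(n_noise + 1)],
        dropped_descriptors=[],
    )
    # independent oracle: a simple threshold on feature 0 is perfect
    assert all((X[i, 0] > 0) == (y[i] == BINDER) for i in range(n))
    return matrix, list(y)


class TestCrossValidate:
    @pytest.mark.parametrize(
        "family", ["logistic_regression", "k_nearest_neighbors", "decision_tree"]
    )
    def test_separable_data_high_f1(self, family):
        matrix, y = _separable_matrix()
        res = cross_validate(matrix, y, family, k_folds=5, seed=0)
        assert res.mean_macro_f1 > 0.95

    def test_null_signal_near_half(self):
        rng = np.random.default_rng(0)
        scores = []
        for seed in range(20):
            matrix, _ = _separable_matrix(n=80, seed=seed)
            y = [BINDER, NON_BINDER] * 40
            y = list(rng.permutation(y))
            res = cross_validate(
                matrix, y, "logistic_regression", k_folds=5, seed=seed
            )
            scores.append(res.mean_macro_f1)
        assert abs(np.mean(scores) - 0.5) < 0.1

    def test_deterministic(self):
        matrix, y = _separable_matrix()
        a = cross_validate(matrix, y, "k_nearest_neighbors", seed=3)
        b = cross_validate(matrix, y, "k_nearest_neighbors", seed=3)
        assert np.array_equal(a.fold_macro_f1, b.fold_macro_f1)

    def test_single_class_fold_errors(self):
        matrix, _ = _separable_matrix(n=20)
        with pytest.raises(ValueError):
            cross_validate(matrix, [BINDER] * 20, "decision_tree")

    def test_k_folds_validation(self):
        matrix, y = _separable_matrix()
        with pytest.raises(ValueError):
            cross_validate(matrix, y, "decision_tree", k_folds=1)

    def test_means_are_fold_averages(self):
        matrix, y = _separable_matrix()
        res = cross_validate(matrix, y, "decision_tree", seed=1)
        assert res.mean_macro_f1 == pytest.approx(res.fold_macro_f1.mean())
        assert np.all((res.fold_macro_f1 >= 0) & (res.fold_macro_f1 <= 1))


class TestSelectFeatures:
    def test_predictive_column_selected(self):
        rng = np.random.default_rng(5)
        n = 100
        y = [BINDER] * 30 + [NON_BINDER] * 70
        signal = np.where(np.array(y) == BINDER, 1.0, 0.0)
        X = np.column_stack([signal] + [rng.normal(size=n) for _ in range(100)])
        matrix = FeatureMatrix(
            ids=[f"c{i}" for i in range(n)],
            X=X,
            feature_ids=["desc:signal"] + [f"desc:noise{j}" for j in range(100)],
            dropped_descriptors=[],
        )
        chosen = select_features(matrix, y, cv_seed=0, selection=SelectionConfig(k_grid=(1, 8)))
        assert "desc:signal" in chosen

    def test_duplicate_column_not_retained_twice(self):
        rng = np.random.default_rng(6)
        n = 60
        y = [BINDER] * 20 + [NON_BINDER] * 40
        signal = np.where(np.array(y) == BINDER, 1.0, 0.0) + rng.normal(0, 0.01, n)
        X = np.column_stack([signal, signal, rng.normal(size=n)])
        matrix = FeatureMatrix(
            ids=[f"c{i}" for i in range(n)],
            X=X,
            feature_ids=["desc:a", "desc:a_copy", "desc:b"],
            dropped_descriptors=[],
        )
        chosen = select_features(matrix, y, cv_seed=0, selection=SelectionConfig(k_grid=(2,)))
        assert not {"desc:a", "desc:a_copy"} <= set(chosen)

    def test_all_constant_returns_empty_with_warning(self, caplog):
        X = np.ones((20, 4))
        matrix = FeatureMatrix(
            ids=[f"c{i}" for i in range(20)],
            X=X,
            feature_ids=[f"desc:k{j}" for j in range(4)],
            dropped_descriptors=[],
        )
        y = [BINDER, NON_BINDER] * 10
        with caplog.at_level(logging.WARNING):
            chosen = select_features(matrix, y, cv_seed=0)
        assert chosen == []
        assert any("constant" in r.message for r in caplog.records)

    def test_too_few_features_errors(self):
        matrix = FeatureMatrix(ids=["a"], X=np.ones((1, 1)), feature_ids=["desc:x"],
                               dropped_descriptors=[])
        with pytest.raises(ValueError):
            select_features(matrix, [BINDER])


def _small_grids():
    return [
        ModelFamily("logistic_regression", {"C": (1.0,), "penalty": ("l2",)}),
        ModelFamily("k_nearest_neighbors", {"n_neighbors": (5,)}),
        ModelFamily("decision_tree", {"max_depth": (3,)}),
    ]


class TestTuneAndTrain:
    def test_linear_signal_prefers_logistic(self):
        # linear-logit ground truth across several seeds
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 150
            X = rng.normal(size=(n, 8))
            logit = X[:, 0] * 2.0 + X[:, 1] - X[:, 2]
            y = [BINDER if v > 0 else NON_BINDER for v in logit]
            matrix = FeatureMatrix(
                ids=[f"r{i}" for i in range(n)],
                X=X,
                feature_ids=[f"desc:x{j}" for j in range(8)],
                dropped_descriptors=[],
            )
            _, per_family = tune_and_train(
                matrix, y, families=_small_grids(), seed=seed,
                selection=SelectionConfig(k_grid=(8,)),
            )
            best = max(per_family.values(), key=lambda r: r.mean_macro_f1)
            wins += best.family == "logistic_regression"
        assert wins >= 8

    def test_deterministic(self, small_matrices):
        Xtr, _, train, _ = small_matrices
        y = [r.binder_label for r in train]
        kwargs = dict(families=_small_grids(), seed=4, selection=SelectionConfig(k_grid=(64,)))
        m1, cv1 = tune_and_train(Xtr, y, **kwargs)
        m2, cv2 = tune_and_train(Xtr, y, **kwargs)
        assert m1.family == m2.family
        assert m1.hyperparameters == m2.hyperparameters
        assert m1.selected_feature_ids == m2.selected_feature_ids
        for fam in cv1:
            assert np.array_equal(cv1[fam].fold_macro_f1, cv2[fam].fold_macro_f1)

    def test_grid_of_one_reduces_to_cv_comparison(self):
        matrix, y = _separable_matrix()
        model, per_family = tune_and_train(
            matrix, y, families=_small_grids(), seed=0,
            selection=SelectionConfig(k_grid=(11,)),
        )
        assert set(per_family) == {
            "logistic_regression", "k_nearest_neighbors", "decision_tree"
        }
        assert model.family in per_family

    def test_single_class_errors(self):
        matrix, _ = _separable_matrix(n=30)
        with pytest.raises(ValueError):
            tune_and_train(matrix, [BINDER] * 30, families=_small_grids())

    def test_empty_families_errors(self):
        matrix, y = _separable_matrix(n=30)
        with pytest.raises(ValueError):
            tune_and_train(matrix, y, families=[])

    def test_empty_grid_value_rejected(self):
        with pytest.raises(ValueError):
            ModelFamily("decision_tree", {"max_depth": ()})


@pytest.fixture(scope="module")
def fitted():
    matrix, y = _separable_matrix()
    model, _ = tune_and_train(
        matrix, y, families=_small_grids(), seed=0,
        selection=SelectionConfig(k_grid=(11,)),
    )
    return model, matrix, y


class TestPredict:

    def test_training_labels_recovered(self, fitted):
        model, matrix, y = fitted
        pred, scores = model.predict(matrix)
        assert pred == y
        assert np.all((scores >= 0) & (scores <= 1))

    def test_row_order_invariance(self, fitted):
        model, matrix, _ = fitted
        perm = np.random.default_rng(0).permutation(matrix.shape[0])
        shuffled = FeatureMatrix(
            ids=[matrix.ids[i] for i in perm],
            X=matrix.X[perm],
            feature_ids=matrix.feature_ids,
            dropped_descriptors=[],
        )
        base = model.predict_scores(matrix)
        assert np.allclose(model.predict_scores(shuffled), base[perm])

    def test_missing_columns_error_lists_them(self, fitted):
        model, matrix, _ = fitted
        crippled = FeatureMatrix(
            ids=matrix.ids,
            X=matrix.X[:, 1:],
            feature_ids=matrix.feature_ids[1:],
            dropped_descriptors=[],
        )
        if model.selected_feature_ids[0] in crippled.feature_ids:
            pytest.skip("first feature not part of the model")
        with pytest.raises(ValueError, match="missing"):
            model.predict(crippled)

    def test_save_load_roundtrip(self, fitted, tmp_path):
        model, matrix, _ = fitted
        model.save(str(tmp_path / "bundle"))
        reloaded = type(model).load(str(tmp_path / "bundle"))
        assert reloaded.family == model.family
        assert reloaded.selected_feature_ids == model.selected_feature_ids
        assert np.allclose(
            reloaded.predict_scores(matrix), model.predict_scores(matrix)
        )
        assert (tmp_path / "bundle.json").exists()


class TestNoLeakage:
    def test_validation_rows_do_not_touch_preprocessing(self):
        # corrupting the validation rows (features and labels alike) must
        # leave every fold's scaler statistics and feature ranking intact
        from fibrilscreen.models import _rank_features, _ScalerState, _prepare_folds

        matrix, y = _separable_matrix(n=60)
        y = np.asarray(y)
        folds = _prepare_folds(matrix.X, y, 3, seed=0)
        rng = np.random.default_rng(1)
        for f in folds:
            X2 = matrix.X.copy()
            X2[f.val_idx] = rng.normal(size=X2[f.val_idx].shape) * 100
            scaler2 = _ScalerState.fit(X2[f.train_idx])
            assert np.array_equal(f.scaler.means, scaler2.means)
            assert np.array_equal(f.scaler.sds, scaler2.sds)
            y01 = (y == BINDER).astype(int)
            ranking2 = _rank_features(
                scaler2.transform(X2[f.train_idx]), y01[f.train_idx], seed=0
            )
            assert np.array_equal(f.ranking, ranking2)
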