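import numpy as np
import pandas as pd
import pytest

import airwayaf as af
from airwayaf.celltyper import (
    CELL_TYPES,
    TypingError,
    evaluate_classifier,
    predict_types,
    split_train_test,
    train_classifier,
)
from airwayaf.features import FEATURE_COLUMNS


class TestSplit:
    def test_206_cells_give_52_test_154_train(self, table206):
        train, test = split_train_test(table206, test_frac=0.25, seed=0)
        assert len(test) == 52 and len(train) == 154
        assert len(set(train) & set(test)) == 0
        assert len(set(train) | set(test)) == len(table206)

    def test_tiny_table_rounding(self):
        table = pd.DataFrame({"cell_type": ["a", "a", "b", "b"]})
        _, test = split_train_test(table, test_frac=0.25, seed=0)
        assert len(test) == 1

    def test_same_seed_reproduces_partition(self, table206):
        a = split_train_test(table206, seed=5)
        b = split_train_test(table206, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_stratification_preserves_class_balance(self, table206):
        train, test = split_train_test(table206, seed=3)
        frac = table206.iloc[test].cell_type.value_counts(normalize=True)
        overall = table206.cell_type.value_counts(normalize=True)
        assert (frac - overall).abs().max() < 0.05

    def test_singleton_class_falls_back_with_warning(self, table206):
        t = table206.copy()
        t.loc[t.index[0], "cell_type"] = "oddball"
        with pytest.warns(UserWarning, match="unstratified"):
            train, test = split_train_test(t, seed=0)
        assert len(train) + len(test) == len(t)


class TestTraining:
    def test_empty_training_set_is_degenerate(self, table206):
        with pytest.raises(TypingError, match="degenerate training data"):
            train_classifier("knn", table206.iloc[:0])

    def test_single_class_is_degenerate(self, table206):
        sub = table206[table206.cell_type == "basal"]
        with pytest.raises(TypingError, match="degenerate training data"):
            train_classifier("multinomial_lr", sub)

    def test_unknown_kind_rejected(self, table206):
        with pytest.raises(TypingError, match="unknown classifier kind"):
            train_classifier("svm", table206)

    def test_k1_knn_memorizes_training_set(self, table206):
        model = train_classifier("knn", table206, n_neighbors=1)
        preds = model.predict(table206)
        assert (preds == table206.cell_type.to_numpy()).all()

    @pytest.mark.parametrize("kind", ["knn", "multinomial_lr", "gradient_boosted"])
    def test_separable_table_trains_to_perfect_accuracy(self, kind):
        # zero within-type spread: supports do not overlap
        params = af.default_type_params()
        for p in params.values():
            p.sds = {k: 0.0 for k in p.sds}
        table = af.sample_feature_table(params=params, n_per_type={t: 10 for t in CELL_TYPES}, seed=0)
        model = train_classifier(kind, table, seed=0)
        report = evaluate_classifier(model, table)
        assert report.accuracy == 1.0 and report.mcc == 1.0


class TestEvaluation:
    def test_all_correct_gives_unit_scores(self, table206):
        model = train_classifier("knn", table206, n_neighbors=1)
        report = evaluate_classifier(model, table206)
        assert report.accuracy == 1.0 and report.mcc == 1.0
        assert report.confusion.sum() == len(table206)
        assert np.array_equal(report.confusion, np.diag(np.diag(report.confusion)))

    def test_random_predictions_have_near_zero_mcc(self, rng):
        """Label-independent predictions on balanced classes give mcc ~ 0
        (mean |mcc| over 1000 permutations stays under 0.15)."""
        from sklearn.metrics import matthews_corrcoef

        y = np.repeat(np.arange(7), 30)[:206]
        mccs = []
        for _ in range(1000):
            mccs.append(matthews_corrcoef(y, rng.permutation(y)))
        assert np.abs(np.mean(mccs)) < 0.02
        assert np.mean(np.abs(mccs)) < 0.15

    def test_multiclass_mcc_matches_binary_closed_form(self, rng):
        from sklearn.metrics import matthews_corrcoef

        y_true = rng.integers(0, 2, 200)
        y_pred = np.where(rng.uniform(size=200) < 0.8, y_true, 1 - y_true)
        tp = int(((y_true == 1) & (y_pred == 1)).sum())
        tn = int(((y_true == 0) & (y_pred == 0)).sum())
        fp = int(((y_true == 0) & (y_pred == 1)).sum())
        fn = int(((y_true == 1) & (y_pred == 0)).sum())
        denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
        closed = (tp * tn - fp * fn) / denom
        assert matthews_corrcoef(y_true, y_pred) == pytest.approx(closed, abs=1e-12)

    def test_importances_normalized_for_boosted_model(self, table206):
        train, test = split_train_test(table206, seed=1)
        model = train_classifier("gradient_boosted", table206.iloc[train], seed=1)
        report = evaluate_classifier(model, table206.iloc[test])
        assert report.importances is not None
        assert sum(report.importances.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in report.importances.values())
        assert set(report.importances) == set(FEATURE_COLUMNS)

    def test_empty_test_set_rejected(self, table206):
        model = train_classifier("knn", table206)
        with pytest.raises(TypingError, match="empty evaluation"):
            evaluate_classifier(model, table206.iloc[:0])

    def test_scaling_leaves_boosted_predictions_unchanged(self, table206):
        """Trees are invariant to monotone per-feature rescaling."""
        train, test = split_train_test(table206, seed=2)
        scaled = table206.copy()
        for i, col in enumerate(FEATURE_COLUMNS):
            scaled[col] = (scaled[col] - scaled[col].mean()) / scaled[col].std()
        m_raw = train_classifier("gradient_boosted", table206.iloc[train], seed=2)
        m_scaled = train_classifier("gradient_boosted", scaled.iloc[train], seed=2)
        assert (
            m_raw.predict(table206.iloc[test]) == m_scaled.predict(scaled.iloc[test])
        ).all()


class TestPrediction:
    def test_predict_types_returns_labels_and_scores(self, table206):
        model = train_classifier("multinomial_lr", table206)
        out = predict_types(model, table206)
        assert list(out.columns) == ["cell_id", "predicted_type", "score"]
        assert set(out.predicted_type) <= set(CELL_TYPES)
        assert ((out.score > 0) & (out.score <= 1)).all()

    def test_missing_feature_column_is_schema_error(self, table206):
        model = train_classifier("knn", table206)
        broken = table206.drop(columns=["ratio"])
        with pytest.raises(TypingError, match="feature schema error"):
            predict_types(model, broken)

    def test_all_missing_row_is_schema_error(self, table206):
        model = train_classifier("knn", table206)
        bad = table206.copy()
        bad.loc[:, FEATURE_COLUMNS] = np.nan
        with pytest.raises(TypingError, match="feature schema error"):
            predict_types(model, bad.iloc[:1])

    def test_secretory_like_row_predicted_secretory(self, table206):
        model = train_classifier("knn", table206)
        params = af.default_type_params()["secretory"]
        row = {"cell_id": 999, "cell_type": None}
        row.update({f: params.means[f] for f in params.means})
        row["aspect_xy"] = row["x_length"] / row["y_length"]
        row["aspect_yz"] = row["y_length"] / row["z_length"]
        row["sd_ratio"] = row["sd_top"] / row["sd_bottom"]
        out = predict_types(model, pd.DataFrame([row]))
        assert out.predicted_type.iloc[0] == "secretory"


class TestAblation:
    def test_dropping_autofluorescence_reduces_mean_mcc(self, table206):
        from airwayaf.celltyper import AUTOFLUORESCENCE_FEATURES, repeated_split_performance

        morph = [f for f in FEATURE_COLUMNS if f not in AUTOFLUORESCENCE_FEATURES]
        full = repeated_split_performance(table206, n_splits=5)
        ablated = repeated_split_performance(table206, n_splits=5, feature_names=morph)
        assert ablated.mcc.mean() < full.mcc.mean()
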