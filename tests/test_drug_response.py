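"""Preprocessing chain (filter, log2, batch adjustment) and ridge pIC50
imputation with its HRD association test."""

import numpy as np
import pandas as pd
import pytest

from hrd_pharmaco.drug_response import (
    batch_adjust,
    delta_pic50_table,
    delta_pic50_test,
    filter_low_expression,
    fit_ridge_models,
    log2_transform,
    predict_pic50,
)
from hrd_pharmaco.io_formats import ExpressionMatrix, Unit
from hrd_pharmaco.synthetic import PharmacoTrainingSet


def _matrix(values, unit=Unit.counts):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values, unit,
    )


class TestFilter:
    def test_more_than_five_zeros_removed(self):
        v = np.ones((2, 20))
        v[0, :6] = 0  # six zeros -> removed
        v[1, :5] = 0  # exactly five -> retained (strict "more than")
        out = filter_low_expression(_matrix(v))
        assert out.gene_ids == ["g1"]

    def test_all_nonzero_unchanged(self):
        m = _matrix(np.ones((3, 8)))
        out = filter_low_expression(m)
        assert out.gene_ids == m.gene_ids
        assert np.array_equal(out.values, m.values)

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            filter_low_expression(_matrix(np.zeros((2, 10))))


class TestLog2:
    def test_pseudocount_examples(self):
        out = log2_transform(_matrix([[0.0, 3.0]]))
        assert out.values[0, 0] == pytest.approx(0.0)
        assert out.values[0, 1] == pytest.approx(2.0)
        assert out.unit is Unit.log2

    def test_monotone(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 100, (1, 50))
        out = log2_transform(_matrix(v)).values[0]
        assert np.all(np.argsort(out) == np.argsort(v[0]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(_matrix([[1.0, -0.5]], unit=Unit.log2))


class TestBatchAdjust:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(8, 1, (20, 12)), unit=Unit.log2)
        out = batch_adjust(m, ["a"] * 12)
        assert np.allclose(out.values, m.values, atol=1e-9)

    def test_planted_shift_removed(self):
        rng = np.random.default_rng(5)
        G, n = 300, 200  # large n per batch
        delta = 1.5
        X = rng.normal(8, 1, (G, 2 * n))
        X[:, n:] += delta
        out = batch_adjust(_matrix(X, unit=Unit.log2), ["a"] * n + ["b"] * n)
        diff = np.abs(out.values[:, n:].mean(axis=1) - out.values[:, :n].mean(axis=1))
        assert diff.mean() < 0.05 * delta

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(6)
        X = rng.normal(8, 1, (100, 60))
        X[:, 30:] += 1.0
        m = _matrix(X, unit=Unit.log2)
        out = batch_adjust(m, ["a"] * 30 + ["b"] * 30)
        assert np.allclose(out.values.mean(axis=1), m.values.mean(axis=1), atol=0.05)

    def test_adjustment_idempotent_to_tolerance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(8, 1, (200, 400))
        X[:, 200:] += 1.2
        labels = ["a"] * 200 + ["b"] * 200
        once = batch_adjust(_matrix(X, unit=Unit.log2), labels)
        twice = batch_adjust(once, labels)
        assert np.abs(twice.values - once.values).mean() < 0.02

    def test_singleton_batch_rejected(self):
        m = _matrix(np.ones((3, 4)), unit=Unit.log2)
        with pytest.raises(ValueError, match="merge"):
            batch_adjust(m, ["a", "a", "a", "b"])

    def test_counts_matrix_rejected(self):
        with pytest.raises(ValueError, match="log2"):
            batch_adjust(_matrix(np.ones((2, 4))), ["a", "a", "b", "b"])


def _tiny_training(small_panel, lines=None):
    lines = lines or list(small_panel.expression.sample_ids)
    return PharmacoTrainingSet(
        expression=small_panel.expression.subset_samples(lines),
        ic50=small_panel.ic50[lines],
        batch_labels=small_panel.batch_labels[lines],
    )


class TestRidge:
    @pytest.fixture(scope="class")
    def imputation(self, small_panel, small_cohort):
        return fit_ridge_models(small_panel, small_cohort.counts, seed=0,
                                alphas=np.logspace(-1, 5, 7))

    def test_one_model_per_drug(self, imputation, small_panel):
        assert len(imputation.models) == small_panel.ic50.shape[0]

    def test_sparse_drug_skipped_with_reason(self, small_panel, small_cohort):
        ic50 = small_panel.ic50.copy()
        ic50.iloc[0, 9:] = np.nan  # 9 non-missing values
        train = PharmacoTrainingSet.__new__(PharmacoTrainingSet)
        train.expression = small_panel.expression
        train.ic50 = ic50
        train.batch_labels = small_panel.batch_labels
        imp = fit_ridge_models(train, small_cohort.counts, seed=0,
                               alphas=np.logspace(-1, 5, 4))
        assert ic50.index[0] in imp.skipped
        assert "9" in imp.skipped[ic50.index[0]]

    def test_constant_ic50_gives_intercept_model(self, small_panel, small_cohort):
        ic50 = small_panel.ic50.copy()
        ic50.iloc[:, :] = np.nan
        ic50.iloc[0, :] = 5.0
        train = _tiny_training(small_panel)
        train.ic50 = ic50.iloc[[0]]
        imp = fit_ridge_models(train, small_cohort.counts, seed=0,
                               alphas=np.logspace(-1, 5, 4))
        model = imp.models[0]
        assert model.intercept == pytest.approx(5.0)
        assert np.abs(model.coefficients).max() < 1e-6
        pred = predict_pic50(imp)
        assert np.allclose(pred.to_numpy(), 5.0, atol=1e-6)

    def test_prediction_invariant_to_patient_gene_order(self, imputation, small_cohort):
        pred1 = predict_pic50(imputation)
        expr = imputation.patient_expr
        perm = np.random.default_rng(3).permutation(expr.n_genes)
        shuffled = ExpressionMatrix(
            [expr.gene_ids[i] for i in perm], list(expr.sample_ids),
            expr.values[perm], expr.unit,
        )
        pred2 = predict_pic50(imputation.models, shuffled)
        assert np.allclose(pred1.to_numpy(), pred2.to_numpy(), atol=1e-9)

    def test_infinite_penalty_predicts_training_mean(self, small_panel, small_cohort):
        imp = fit_ridge_models(small_panel, small_cohort.counts, seed=0,
                               penalty_strategy="fixed", alphas=[1e12])
        pred = predict_pic50(imp)
        for model in imp.models:
            mean_ic50 = small_panel.ic50.loc[model.drug_id].mean()
            assert np.allclose(pred.loc[model.drug_id], mean_ic50, atol=0.05)

    def test_unit_mismatch_rejected(self, imputation, small_cohort):
        with pytest.raises(ValueError, match="unit"):
            imputation.models[0].predict(small_cohort.counts.subset_genes(
                imputation.models[0].genes))


class TestDeltaPIC50:
    def test_identical_groups_null(self):
        row = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                        index=[f"p{i}" for i in range(6)])
        status = pd.Series(["HR_proficient"] * 3 + ["HR_deficient"] * 3, index=row.index)
        res = delta_pic50_test(row, status)
        assert res["delta_pic50"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_exact_p_on_separated_groups(self):
        row = pd.Series([1, 2, 3, 4, 5, 6], index=[f"p{i}" for i in range(6)], dtype=float)
        status = pd.Series(["HR_proficient"] * 3 + ["HR_deficient"] * 3, index=row.index)
        res = delta_pic50_test(row, status)
        assert res["p_value"] == pytest.approx(0.1)
        assert res["delta_pic50"] == pytest.approx(-3.0)

    def test_empty_group_untestable(self):
        row = pd.Series([1.0, 2.0], index=["a", "b"])
        status = pd.Series(["HR_deficient", "HR_deficient"], index=row.index)
        res = delta_pic50_test(row, status)
        assert not res["testable"]

    def test_family_fdr_at_least_p(self):
        rng = np.random.default_rng(4)
        pic50 = pd.DataFrame(rng.normal(size=(6, 30)),
                             index=[f"d{i}" for i in range(6)],
                             columns=[f"p{i}" for i in range(30)])
        status = pd.Series(["HR_proficient"] * 15 + ["HR_deficient"] * 15,
                           index=pic50.columns)
        table = delta_pic50_table(pic50, status)
        ok = table["p_value"].notna()
        assert (table.loc[ok, "fdr"] >= table.loc[ok, "p_value"] - 1e-12).all()
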