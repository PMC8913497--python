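"""HRD signature derivation: size factors, NB Wald DE, threshold
selection, purity filter, and the lasso-logistic HRD score."""

import numpy as np
import pandas as pd
import pytest

from hrd_pharmaco.drug_response import log2_transform
from hrd_pharmaco.io_formats import ExpressionMatrix, Unit
from hrd_pharmaco.signature import (
    HRDScoreModel,
    estimate_size_factors,
    fit_hrd_score,
    nb_wald_test,
    predict_hrd_score,
    purity_filter,
    select_signature,
)
from hrd_pharmaco.stats import roc_auc


def _matrix(values, unit=Unit.counts):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values, unit,
    )


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        f = estimate_size_factors(np.array([[10, 10], [3, 3], [7, 7]]))
        assert np.allclose(f, [1.0, 1.0])

    def test_double_depth_gives_2x_factor(self):
        a = np.array([[10.0], [20.0], [5.0]])
        f = estimate_size_factors(np.hstack([a, 2 * a]))
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_three_gene_hand_example(self):
        # geomeans: g0 sqrt(2*8)=4, g1 sqrt(4*16)=8, g2 sqrt(1*9)=3
        # ratios s0: (0.5, 0.5, 1/3) -> median 0.5; s1: (2, 2, 3) -> median 2
        counts = np.array([[2, 8], [4, 16], [1, 9]], dtype=float)
        f = estimate_size_factors(counts)
        assert np.allclose(f, [0.5, 2.0])

    def test_fallback_when_no_all_positive_gene(self):
        counts = np.array([[0, 4], [6, 0]], dtype=float)
        with pytest.warns(UserWarning, match="positive"):
            f = estimate_size_factors(counts)
        assert (f > 0).all()


class TestNBWald:
    def test_requires_two_groups_of_three(self, small_cohort):
        with pytest.raises(ValueError, match="two groups"):
            nb_wald_test(small_cohort.counts, ["a"] * small_cohort.counts.n_samples)

    def test_duplicate_gene_rows_get_identical_statistics(self):
        rng = np.random.default_rng(0)
        base = rng.negative_binomial(10, 0.1, size=(1, 16)).astype(float)
        other = rng.negative_binomial(10, 0.1, size=(6, 16)).astype(float)
        counts = np.vstack([base, base, other])
        m = _matrix(counts)
        de = nb_wald_test(m, ["a"] * 8 + ["b"] * 8)
        assert de.loc["g0", "log2_fold_change"] == pytest.approx(
            de.loc["g1", "log2_fold_change"], abs=1e-6
        )
        assert de.loc["g0", "p_value"] == pytest.approx(de.loc["g1", "p_value"], rel=1e-6)

    def test_planted_fold_change_estimated_accurately(self):
        """3-fold genes at n = 100/100, dispersion 0.1: estimated log2FC
        within +-0.2 of log2(3) for >= 90% of planted genes. The planted
        fraction is kept at ~5% so the median-of-ratios size factors are
        not dragged by the DE genes."""
        rng = np.random.default_rng(12)
        n, g_planted, g_null = 100, 20, 380
        disp = 0.1
        r = 1 / disp
        base = np.clip(rng.lognormal(np.log(100), 1.0, g_planted + g_null), 10, None)
        mu = np.repeat(base[:, None], 2 * n, axis=1)
        mu[:g_planted, n:] *= 3.0
        counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
        de = nb_wald_test(_matrix(counts), ["a"] * n + ["b"] * n)
        lfc = de.iloc[:g_planted]["log2_fold_change"]
        assert (np.abs(lfc - np.log2(3.0)) <= 0.2).mean() >= 0.9

    def test_fdr_at_least_p(self, small_cohort, small_status):
        de = nb_wald_test(small_cohort.counts, small_status.reindex(small_cohort.counts.sample_ids))
        ok = de["p_value"].notna()
        assert (de.loc[ok, "fdr"] >= de.loc[ok, "p_value"] - 1e-12).all()


class TestSelectSignature:
    def test_reported_examples(self):
        de = pd.DataFrame(
            {
                "log2_fold_change": [np.log2(6.63), np.log2(0.05), np.log2(2.9)],
                "fdr": [7.15e-08, 2.32e-10, 1e-10],
                "p_value": [1e-9, 1e-11, 1e-11],
                "base_mean": [10.0, 10.0, 10.0],
            },
            index=["RASGEF1C", "CALML3", "NEARMISS"],
        )
        up, down = select_signature(de)
        assert up == ["RASGEF1C"]        # FC 6.63 at tiny FDR
        assert down == ["CALML3"]        # FC 0.05
        assert "NEARMISS" not in up      # FC 2.9 fails the fold threshold

    def test_fdr_boundary_inclusive(self):
        de = pd.DataFrame(
            {"log2_fold_change": [2.0], "fdr": [0.01], "p_value": [0.001], "base_mean": [5.0]},
            index=["gX"],
        )
        up, _ = select_signature(de)
        assert up == ["gX"]


class TestPurityFilter:
    def _expr_and_purity(self, n=20):
        rng = np.random.default_rng(5)
        purity = pd.Series(rng.uniform(0.3, 0.9, n), index=[f"s{j}" for j in range(n)])
        neg = -purity.to_numpy()                      # exact negative monotone
        pos = purity.to_numpy() * 2.0                 # strong positive
        indep = rng.normal(size=n)
        values = np.vstack([neg, pos, indep])
        return _matrix(values, unit=Unit.log2), purity

    def test_negative_gene_removed_positive_retained(self):
        expr, purity = self._expr_and_purity()
        sig = purity_filter((["g0", "g1", "g2"], []), expr, purity)
        assert "g0" not in sig.up_genes          # R = -1
        assert "g1" in sig.up_genes              # one-sided rule on sign
        removed = sig.provenance["purity_filter"]["removed"]
        assert removed["g0"]["rho"] == pytest.approx(-1.0)

    def test_independent_gene_usually_retained(self):
        rng = np.random.default_rng(9)
        n, reps, removed = 30, 60, 0
        for _ in range(reps):
            purity = pd.Series(rng.uniform(0.3, 0.9, n), index=[f"s{j}" for j in range(n)])
            expr = _matrix(rng.normal(size=(1, n)), unit=Unit.log2)
            sig = purity_filter((["g0"], []), expr, purity)
            removed += "g0" not in sig.up_genes
        # one-sided 5% rule: false-removal should be near 2.5-5%
        assert removed / reps <= 0.12

    def test_constant_purity_skips_filter(self):
        expr = _matrix(np.random.default_rng(0).normal(size=(2, 12)), unit=Unit.log2)
        purity = pd.Series(0.5, index=expr.sample_ids)
        with pytest.warns(UserWarning, match="constant purity"):
            sig = purity_filter((["g0"], ["g1"]), expr, purity)
        assert sig.up_genes == ["g0"] and sig.down_genes == ["g1"]


class TestHRDScore:
    def _separable(self, n=60, p=12, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(p, n))
        X[0] += 4.0 * y  # one strongly separating gene
        X[1] -= 4.0 * y
        expr = _matrix(X, unit=Unit.log2)
        return expr, y

    def test_separable_data_trains_to_auc_one(self):
        expr, y = self._separable()
        model = fit_hrd_score(expr, y, n_refits=3, n_lambda=30, seed=0)
        scores = predict_hrd_score(model, expr)
        assert roc_auc(scores.to_numpy(), y) == pytest.approx(1.0)
        assert ((scores > 0.5).to_numpy().astype(int) == y).mean() >= 0.95

    def test_cross_validated_auc_high_when_separable(self):
        expr, y = self._separable(n=80, seed=3)
        folds = np.arange(80) % 5
        aucs = []
        for f in range(5):
            tr = folds != f
            m = fit_hrd_score(expr.subset_samples([expr.sample_ids[i] for i in np.where(tr)[0]]),
                              y[tr], n_refits=0, n_lambda=20, seed=f)
            sc = predict_hrd_score(m, expr.subset_samples(
                [expr.sample_ids[i] for i in np.where(~tr)[0]]))
            aucs.append(roc_auc(sc.to_numpy(), y[~tr]))
        assert np.mean(aucs) >= 0.95

    def test_permuted_labels_give_chance_cv_auc(self):
        rng = np.random.default_rng(21)
        n, p = 80, 10
        expr = _matrix(rng.normal(size=(p, n)), unit=Unit.log2)
        y = rng.permutation(np.array([0, 1] * (n // 2)))
        folds = np.arange(n) % 5
        aucs = []
        for f in range(5):
            tr = folds != f
            m = fit_hrd_score(expr.subset_samples([expr.sample_ids[i] for i in np.where(tr)[0]]),
                              y[tr], n_refits=0, n_lambda=15, seed=f)
            sc = predict_hrd_score(m, expr.subset_samples(
                [expr.sample_ids[i] for i in np.where(~tr)[0]]))
            aucs.append(roc_auc(sc.to_numpy(), y[~tr]))
        assert abs(np.mean(aucs) - 0.5) <= 0.12

    def test_single_class_rejected(self):
        expr, _ = self._separable(n=20)
        with pytest.raises(ValueError, match="single class"):
            fit_hrd_score(expr, np.zeros(20, dtype=int), n_refits=0)

    def test_selection_frequencies_favor_signal_genes(self):
        expr, y = self._separable(n=60, seed=5)
        model = fit_hrd_score(expr, y, n_refits=20, n_lambda=20, seed=0)
        stab = model.stability_weights
        signal = stab.loc[["g0", "g1"], "selection_freq"].mean()
        noise = stab.drop(["g0", "g1"])["selection_freq"].mean()
        assert signal > noise

    def test_predict_all_zero_input_gives_logistic_intercept(self):
        model = HRDScoreModel(
            genes=["g0", "g1"], weights=np.array([1.0, -2.0]), intercept=0.4,
            lambda_=0.1, cv_error_curve=pd.DataFrame(),
            stability_weights=pd.DataFrame(), gene_means=np.zeros(2),
            gene_sds=np.ones(2),
        )
        expr = _matrix(np.zeros((2, 3)), unit=Unit.log2)
        scores = predict_hrd_score(model, expr)
        assert np.allclose(scores, 1.0 / (1.0 + np.exp(-0.4)))

    def test_score_increases_in_positively_weighted_gene(self):
        model = HRDScoreModel(
            genes=["g0"], weights=np.array([1.5]), intercept=0.0,
            lambda_=0.1, cv_error_curve=pd.DataFrame(),
            stability_weights=pd.DataFrame(), gene_means=np.zeros(1),
            gene_sds=np.ones(1),
        )
        expr = _matrix(np.array([[0.0, 1.0, 2.0]]), unit=Unit.log2)
        scores = predict_hrd_score(model, expr).to_numpy()
        assert np.all(np.diff(scores) > 0)

    def test_missing_model_genes_listed(self):
        model = HRDScoreModel(
            genes=["gX"], weights=np.array([1.0]), intercept=0.0, lambda_=0.1,
            cv_error_curve=pd.DataFrame(), stability_weights=pd.DataFrame(),
            gene_means=np.zeros(1), gene_sds=np.ones(1),
        )
        with pytest.raises(KeyError, match="gX"):
            predict_hrd_score(model, _matrix(np.zeros((1, 2)), unit=Unit.log2))
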