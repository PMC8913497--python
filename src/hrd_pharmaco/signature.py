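"""HRD transcriptomic signature: differential expression between genomic
HRD groups, purity filtering, and a lasso-logistic transcriptomic HRD
score.

The differential-expression stage is a negative-binomial Wald test with
median-of-ratios size factors and trend-shrunk gene-wise dispersions
(DESeq2 model, computed through pydeseq2 with outlier refitting and
independent filtering disabled). Signature membership requires FDR <= 0.01
and fold change >= 3 (up) or <= 1/3 (down); genes whose expression
correlates negatively with tumor purity (Spearman R < 0, p <= 0.05) are
then removed, since their apparent association with HRD can be driven by
stromal admixture rather than tumor biology.

The transcriptomic HRD score is a lasso-penalized logistic regression of
genomic HRD status on the signature genes' expression: the penalty is
chosen by 10-fold cross-validation over a log-spaced grid (binomial
deviance by default), per-gene selection stability is estimated by
repeated refits over resampled fold assignments, and the score is the
fitted probability in (0, 1), classified at 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io_formats import ExpressionMatrix, Unit
from .stats import bh_fdr, roc_auc, spearman

logger = logging.getLogger(__name__)

__all__ = [
    "HRDSignature",
    "HRDScoreModel",
    "estimate_size_factors",
    "nb_wald_test",
    "select_signature",
    "purity_filter",
    "fit_hrd_score",
    "predict_hrd_score",
    "roc_auc",
]


def estimate_size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors.

    factor_s = median over reference genes of count_gs / geomean_g, where
    reference genes have all-positive counts. If no gene is positive in
    every sample, fall back (with a warning) to per-gene geometric means
    over positive entries and per-sample medians over positive counts.
    """
    if isinstance(counts, ExpressionMatrix):
        X = counts.values
    else:
        X = np.asarray(counts, dtype=float)
    if X.ndim != 2:
        raise ValueError("counts must be a genes x samples matrix")
    all_pos = (X > 0).all(axis=1)
    if all_pos.any():
        ref = X[all_pos]
        log_geomean = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_geomean[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no gene positive in all samples; falling back to positive-subset ratios",
            stacklevel=2,
        )
        with np.errstate(divide="ignore"):
            logX = np.where(X > 0, np.log(X), np.nan)
        log_geomean = np.nanmean(logX, axis=1)
        ratios = logX - log_geomean[:, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    if not (factors > 0).all():
        raise ValueError("non-positive size factor estimated")
    return factors


def nb_wald_test(counts: ExpressionMatrix, group_labels, size_factors=None) -> pd.DataFrame:
    """Negative-binomial Wald test between two groups.

    Returns a DataFrame (index gene_id) with base_mean, log2_fold_change
    (group "HR_deficient" vs "HR_proficient", or second-vs-first label
    otherwise), p_value and BH fdr. All-zero genes are excluded and
    reported via logging. Requires both groups to have n >= 3.
    """
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    labels = pd.Series(list(group_labels), index=counts.sample_ids, name="condition")
    levels = list(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    n_per = labels.value_counts()
    if (n_per < 3).any():
        raise ValueError(f"each group needs n >= 3, got {dict(n_per)}")
    if "HR_deficient" in levels and "HR_proficient" in levels:
        test_level, ref_level = "HR_deficient", "HR_proficient"
    else:
        test_level, ref_level = levels[1], levels[0]

    mat = pd.DataFrame(
        counts.values.T.astype(int), index=counts.sample_ids, columns=counts.gene_ids
    )
    all_zero = [g for g in mat.columns if (mat[g] == 0).all()]
    if all_zero:
        logger.warning("excluding %d all-zero gene(s) from the Wald test", len(all_zero))
        mat = mat.drop(columns=all_zero)
    meta = labels.to_frame()
    if size_factors is not None:
        logger.info(
            "size factors are recomputed by the DE backend with the same "
            "median-of-ratios estimator; the provided vector is ignored"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=mat, metadata=meta, design="~condition", quiet=True,
                           refit_cooks=False)
        dds.deseq2()
        ds = DeseqStats(
            dds,
            contrast=["condition", test_level, ref_level],
            cooks_filter=False,
            independent_filter=False,
            quiet=True,
        )
        ds.summary()
    res = ds.results_df
    out = pd.DataFrame(
        {
            "base_mean": res["baseMean"],
            "log2_fold_change": res["log2FoldChange"],
            "p_value": res["pvalue"],
        }
    )
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out.index.name = "gene_id"
    return out


def select_signature(de: pd.DataFrame, fdr_max: float = 0.01, fc_min: float = 3.0):
    """Provisional up/down gene lists: up iff fdr <= fdr_max and fold
    change >= fc_min; down iff fdr <= fdr_max and fold change <= 1/fc_min
    (fold change = 2**log2_fold_change)."""
    fc = np.exp2(de["log2_fold_change"])
    sig = de["fdr"] <= fdr_max
    up = list(de.index[sig & (fc >= fc_min)])
    down = list(de.index[sig & (fc <= 1.0 / fc_min)])
    return up, down


@dataclass
class HRDSignature:
    up_genes: list[str]
    down_genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene lists overlap")

    @property
    def genes(self) -> list[str]:
        return list(self.up_genes) + list(self.down_genes)


def purity_filter(
    candidates: tuple[list[str], list[str]],
    expression: ExpressionMatrix,
    purity: pd.Series,
    p_max: float = 0.05,
) -> HRDSignature:
    """Remove candidate genes whose expression is significantly negatively
    Spearman-correlated with tumor purity (R < 0 and p <= p_max; the rule
    is one-sided on the sign). Constant purity skips the filter with a
    warning. Removals are logged with their statistics."""
    up, down = candidates
    purity = purity.reindex(expression.sample_ids)
    if purity.isna().any():
        raise ValueError("purity missing for some samples")
    if purity.nunique() < 2:
        warnings.warn("constant purity vector: purity filter skipped", stacklevel=2)
        return HRDSignature(list(up), list(down), provenance={"purity_filter": "skipped"})
    if len(purity) < 10:
        raise ValueError("purity filter needs >= 10 samples")
    removed = {}

    def _keep(genes):
        kept = []
        for g in genes:
            x = expression.subset_genes([g]).values[0]
            res = spearman(x, purity.to_numpy())
            if res.rho < 0 and res.p_value <= p_max:
                removed[g] = {"rho": res.rho, "p_value": res.p_value}
                logger.info("purity filter removed %s (rho=%.3f, p=%.3g)", g, res.rho, res.p_value)
            else:
                kept.append(g)
        return kept

    return HRDSignature(
        up_genes=_keep(up),
        down_genes=_keep(down),
        provenance={"purity_filter": {"p_max": p_max, "removed": removed}},
    )


@dataclass
class HRDScoreModel:
    genes: list[str]
    weights: np.ndarray  # sparse: non-selected genes are exactly 0
    intercept: float
    lambda_: float
    cv_error_curve: pd.DataFrame  # columns: lambda, cv_error
    stability_weights: pd.DataFrame  # gene, selection_freq, mean_weight, sd_weight
    gene_means: np.ndarray
    gene_sds: np.ndarray
    threshold: float = 0.5

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if len(self.weights) != len(self.genes):
            raise ValueError("weight vector length must match gene list")


def _lasso_path_cv(Xs, y, lambdas, n_folds, rng) -> np.ndarray:
    """Mean binomial deviance per lambda over stratified K-fold CV."""
    n = len(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(0, 2**31 - 1)))
    dev = np.zeros(len(lambdas))
    for tr_idx, va_idx in skf.split(Xs, y):
        for j, lam in enumerate(lambdas):
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (lam * len(tr_idx)), solver="liblinear",
                max_iter=200, tol=1e-6, random_state=0,
            )
            clf.fit(Xs[tr_idx], y[tr_idx])
            p = clf.predict_proba(Xs[va_idx])[:, 1]
            p = np.clip(p, 1e-12, 1 - 1e-12)
            yv = y[va_idx]
            dev[j] += -2.0 * float(np.sum(yv * np.log(p) + (1 - yv) * np.log(1 - p)))
    return dev / n


def _misclass_cv(Xs, y, lambdas, n_folds, rng) -> np.ndarray:
    n = len(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(0, 2**31 - 1)))
    err = np.zeros(len(lambdas))
    for tr_idx, va_idx in skf.split(Xs, y):
        for j, lam in enumerate(lambdas):
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (lam * len(tr_idx)), solver="liblinear",
                max_iter=200, tol=1e-6, random_state=0,
            )
            clf.fit(Xs[tr_idx], y[tr_idx])
            err[j] += float(np.sum(clf.predict(Xs[va_idx]) != y[va_idx]))
    return err / n


def fit_hrd_score(
    expression: ExpressionMatrix,
    labels,
    genes=None,
    n_folds: int = 10,
    n_refits: int = 300,
    seed: int = 0,
    n_lambda: int = 100,
    refit_n_lambda: int = 25,
    error_metric: str = "deviance",
) -> HRDScoreModel:
    """Lasso-logistic transcriptomic HRD score.

    The lambda grid holds ``n_lambda`` values log-spaced between
    lambda_max (the smallest penalty zeroing all coefficients) and
    lambda_max * 1e-4; lambda* minimizes the CV error ("deviance" by
    default, "misclassification" by config); ``n_refits`` refits over
    resampled fold assignments give per-gene selection frequencies
    (each refit re-searches a coarser ``refit_n_lambda``-point grid over
    the same range); the final model is refit at lambda* on all data.
    """
    if genes is None:
        genes = list(expression.gene_ids)
    sub = expression.subset_genes(genes)
    y = np.asarray(
        [1 if str(v) in ("1", "HR_deficient", "True") else 0 for v in labels], dtype=int
    )
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = sub.values.T  # samples x genes
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    Xs = (X - means) / sds
    n = len(y)

    ybar = y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ (y - ybar))) / n)
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), n_lambda)

    rng = np.random.default_rng(seed)
    cv_fn = _lasso_path_cv if error_metric == "deviance" else _misclass_cv
    errors = cv_fn(Xs, y, lambdas, n_folds, rng)
    best = int(np.argmin(errors))
    lam_star = float(lambdas[best])
    curve = pd.DataFrame({"lambda": lambdas, "cv_error": errors})

    # stability: refit with resampled fold assignments, collect weights
    sel = np.zeros(len(genes))
    wsum = np.zeros(len(genes))
    wsq = np.zeros(len(genes))
    refit_lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), refit_n_lambda)
    for _ in range(n_refits):
        err_r = cv_fn(Xs, y, refit_lambdas, n_folds, rng)
        lam_r = float(refit_lambdas[int(np.argmin(err_r))])
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (lam_r * n), solver="liblinear", max_iter=500, tol=1e-6, random_state=0
        )
        clf.fit(Xs, y)
        w = clf.coef_[0]
        sel += (w != 0).astype(float)
        wsum += w
        wsq += w**2
    if n_refits > 0:
        freq = sel / n_refits
        mean_w = wsum / n_refits
        sd_w = np.sqrt(np.maximum(wsq / n_refits - mean_w**2, 0.0))
    else:
        freq = mean_w = sd_w = np.zeros(len(genes))
    stability = pd.DataFrame(
        {"gene": genes, "selection_freq": freq, "mean_weight": mean_w, "sd_weight": sd_w}
    ).set_index("gene")

    final = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (lam_star * n), solver="liblinear", max_iter=500, tol=1e-6, random_state=0
    )
    final.fit(Xs, y)
    return HRDScoreModel(
        genes=list(genes),
        weights=final.coef_[0],
        intercept=float(final.intercept_[0]),
        lambda_=lam_star,
        cv_error_curve=curve,
        stability_weights=stability,
        gene_means=means,
        gene_sds=sds,
    )


def predict_hrd_score(model: HRDScoreModel, expression: ExpressionMatrix) -> pd.Series:
    """Per-sample transcriptomic HRD score in (0,1):
    logistic(intercept + sum w * standardized expression)."""
    missing = [g for g in model.genes if g not in set(expression.gene_ids)]
    if missing:
        raise KeyError(f"expression matrix missing model genes: {missing[:10]}")
    sub = expression.subset_genes(model.genes)
    Xs = (sub.values - model.gene_means[:, None]) / model.gene_sds[:, None]
    score = expit(model.intercept + model.weights @ Xs)
    return pd.Series(score, index=expression.sample_ids, name="hrd_score")
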