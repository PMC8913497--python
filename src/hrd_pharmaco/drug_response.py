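"""Drug-sensitivity imputation: cell-line panel -> patient pIC50.

The training panel (cell-line expression + per-drug log-IC50) and the
patient cohort are homogenized by a shared preprocessing chain — low-
expression filter, log2 transform, and a parametric empirical-Bayes
location/scale batch adjustment with cohort (train vs test) as the batch
variable — then one ridge-regression model per drug maps standardized
expression to log-IC50 and is applied to patients. Lower predicted pIC50
means more sensitive. The per-drug HRD association is a two-sided Wilcoxon
rank-sum test on pIC50 between HR-proficient and HR-deficient patients,
with

    delta_pIC50 = mean(proficient) - mean(deficient)

so delta > 0 flags a drug as more potent in HR-deficient tumors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .io_formats import ExpressionMatrix, Unit
from .stats import bh_fdr, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "filter_low_expression",
    "log2_transform",
    "batch_adjust",
    "homogenize",
    "RidgeDrugModel",
    "RidgeImputation",
    "fit_ridge_models",
    "predict_pic50",
    "delta_pic50_test",
    "delta_pic50_table",
]


def filter_low_expression(matrix: ExpressionMatrix, max_zero_samples: int = 5) -> ExpressionMatrix:
    """Keep genes whose expression is exactly zero in at most
    ``max_zero_samples`` samples ("more than five" is strict); order
    preserved. Empty result is an error."""
    zeros = (matrix.values == 0).sum(axis=1)
    keep = zeros <= max_zero_samples
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(matrix.sample_ids), matrix.values[keep], matrix.unit)


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """value -> log2(value + pseudocount); unit becomes log2."""
    if np.nanmin(matrix.values) < 0:
        raise ValueError("negative values cannot be log2-transformed")
    return ExpressionMatrix(
        list(matrix.gene_ids),
        list(matrix.sample_ids),
        np.log2(matrix.values + pseudocount),
        Unit.log2,
    )


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m**2) / s2 if s2 > 0 else 2.0


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m**3) / s2 if s2 > 0 else 1.0


def batch_adjust(matrix: ExpressionMatrix, batch_labels, max_iter: int = 100) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment on a
    log2-scale matrix.

    Per gene, batch means and variances are shrunk toward common priors
    (normal for locations, inverse-gamma for scales) and removed; the
    per-gene grand mean is preserved. A single batch is an identity
    (logged); a batch with one sample is an error suggesting a merge.
    """
    if matrix.unit is not Unit.log2:
        raise ValueError("batch_adjust expects a log2-scale matrix")
    labels = pd.Series(list(batch_labels), index=matrix.sample_ids)
    batches = labels.unique()
    if len(batches) == 1:
        logger.info("single batch: batch adjustment is the identity")
        return ExpressionMatrix(
            list(matrix.gene_ids), list(matrix.sample_ids), matrix.values.copy(), matrix.unit
        )
    counts = labels.value_counts()
    singles = counts[counts < 2]
    if len(singles):
        raise ValueError(
            f"batches with a single sample: {list(singles.index)}; merge them with "
            "a neighboring batch before adjustment"
        )
    X = matrix.values.astype(float)
    G, S = X.shape
    masks = {b: (labels == b).to_numpy() for b in batches}
    n_b = {b: masks[b].sum() for b in batches}

    batch_means = np.column_stack([X[:, masks[b]].mean(axis=1) for b in batches])
    weights = np.array([n_b[b] / S for b in batches])
    alpha = batch_means @ weights  # per-gene grand mean (sample-size weighted)
    resid = X.copy()
    for j, b in enumerate(batches):
        resid[:, masks[b]] -= batch_means[:, [j]]
    sigma2 = (resid**2).mean(axis=1)
    sigma = np.sqrt(np.where(sigma2 > 0, sigma2, 1.0))
    constant = sigma2 <= 0

    Z = (X - alpha[:, None]) / sigma[:, None]
    adjusted = np.empty_like(Z)
    for b in batches:
        m = masks[b]
        zb = Z[:, m]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        delta_hat = np.where(delta_hat > 0, delta_hat, 1e-8)
        gamma_bar, tau2 = gamma_hat.mean(), gamma_hat.var()
        a_pr, b_pr = _aprior(delta_hat), _bprior(delta_hat)
        g_star, d_star = gamma_hat.copy(), delta_hat.copy()
        nb = n_b[b]
        for _ in range(max_iter):
            g_new = (nb * tau2 * gamma_hat + d_star * gamma_bar) / (nb * tau2 + d_star)
            ss = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_pr + 0.5 * ss) / (nb / 2.0 + a_pr - 1.0)
            if max(np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max()) < 1e-8:
                g_star, d_star = g_new, d_new
                break
            g_star, d_star = g_new, d_new
        adjusted[:, m] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]
    out = adjusted * sigma[:, None] + alpha[:, None]
    out[constant] = X[constant]
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), out, Unit.log2)


def homogenize(
    train_expr: ExpressionMatrix,
    patient_expr: ExpressionMatrix,
    max_zero_samples: int = 5,
    pseudocount: float = 1.0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Shared preprocessing of the training panel and patient cohort:
    intersect genes, filter low expression jointly, log2, and batch-adjust
    the combined matrix with cohort (train vs test) as the batch."""
    shared = [g for g in train_expr.gene_ids if g in set(patient_expr.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between training panel and patient cohort")
    tr = train_expr.subset_genes(shared)
    pt = patient_expr.subset_genes(shared)
    combined = ExpressionMatrix(
        shared,
        list(tr.sample_ids) + list(pt.sample_ids),
        np.hstack([tr.values, pt.values]),
        Unit.counts,
    )
    combined = filter_low_expression(combined, max_zero_samples=max_zero_samples)
    combined = log2_transform(combined, pseudocount=pseudocount)
    cohort = ["train"] * tr.n_samples + ["test"] * pt.n_samples
    combined = batch_adjust(combined, cohort)
    tr_out = combined.subset_samples(tr.sample_ids)
    pt_out = combined.subset_samples(pt.sample_ids)
    return tr_out, pt_out


@dataclass
class RidgeDrugModel:
    """One ridge model per drug mapping standardized log2 expression to
    log-IC50. Standardization (per-gene mean/sd) is estimated on the
    training lines and stored with the model."""

    drug_id: str
    genes: list[str]
    coefficients: np.ndarray
    intercept: float
    penalty: float
    n_train: int
    cv_mse: float
    gene_means: np.ndarray
    gene_sds: np.ndarray

    def __post_init__(self):
        if len(self.coefficients) != len(self.genes):
            raise ValueError("coefficient vector length must match gene list")
        if self.penalty <= 0:
            raise ValueError("ridge penalty must be positive")

    def predict(self, matrix: ExpressionMatrix) -> pd.Series:
        if matrix.unit is not Unit.log2:
            raise ValueError("unit mismatch: ridge models expect log2 expression")
        missing = [g for g in self.genes if g not in set(matrix.gene_ids)]
        if missing:
            raise KeyError(f"patient matrix missing model genes: {missing[:10]}")
        sub = matrix.subset_genes(self.genes)
        Xs = (sub.values - self.gene_means[:, None]) / self.gene_sds[:, None]
        pred = self.intercept + self.coefficients @ Xs
        return pd.Series(pred, index=matrix.sample_ids, name=self.drug_id)


@dataclass
class RidgeImputation:
    models: list[RidgeDrugModel]
    patient_expr: ExpressionMatrix  # homogenized patient matrix
    skipped: dict[str, str]

    def __iter__(self):
        return iter(self.models)


def _fit_one_drug(
    drug: str,
    y: pd.Series,
    train: ExpressionMatrix,
    alphas: np.ndarray,
    n_folds: int,
    seed: int,
) -> RidgeDrugModel:
    lines = [s for s in y.index if not np.isnan(y[s])]
    sub = train.subset_samples(lines)
    X = sub.values.T  # lines x genes
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    Xs = (X - means) / sds
    yv = y[lines].to_numpy()

    if len(alphas) == 1:
        final = Ridge(alpha=float(alphas[0]))
        final.fit(Xs, yv)
        return RidgeDrugModel(
            drug_id=drug, genes=list(train.gene_ids), coefficients=final.coef_,
            intercept=float(final.intercept_), penalty=float(alphas[0]),
            n_train=len(lines), cv_mse=float("nan"), gene_means=means, gene_sds=sds,
        )
    best_alpha, best_mse = alphas[0], np.inf
    kf = KFold(n_splits=min(n_folds, len(lines)), shuffle=True, random_state=seed)
    folds = list(kf.split(Xs))
    for a in alphas:
        mse = 0.0
        for tr_idx, va_idx in folds:
            model = Ridge(alpha=a)
            model.fit(Xs[tr_idx], yv[tr_idx])
            err = yv[va_idx] - model.predict(Xs[va_idx])
            mse += float(err @ err)
        mse /= len(lines)
        if mse < best_mse:
            best_mse, best_alpha = mse, a
    final = Ridge(alpha=best_alpha)
    final.fit(Xs, yv)
    return RidgeDrugModel(
        drug_id=drug,
        genes=list(train.gene_ids),
        coefficients=final.coef_,
        intercept=float(final.intercept_),
        penalty=float(best_alpha),
        n_train=len(lines),
        cv_mse=best_mse,
        gene_means=means,
        gene_sds=sds,
    )


def fit_ridge_models(
    train,
    patient_expr: ExpressionMatrix,
    penalty_strategy: str = "cv10",
    alphas=None,
    seed: int = 0,
    max_zero_samples: int = 5,
    pseudocount: float = 1.0,
) -> RidgeImputation:
    """Fit one ridge model per drug with >=10 non-missing IC50 values.

    ``train`` is a PharmacoTrainingSet (raw counts); preprocessing runs the
    homogenization chain jointly with ``patient_expr``. The penalty is
    chosen by 10-fold CV minimizing MSE over a log-spaced grid (fixed
    seed). Drugs with <10 values are skipped with a logged reason.
    """
    if penalty_strategy not in ("cv10", "fixed"):
        raise ValueError(f"unknown penalty strategy {penalty_strategy!r}")
    if alphas is None:
        alphas = np.logspace(-2, 6, 17)
    else:
        alphas = np.asarray(alphas, dtype=float)
    tr_expr, pt_expr = homogenize(
        train.expression, patient_expr,
        max_zero_samples=max_zero_samples, pseudocount=pseudocount,
    )
    models: list[RidgeDrugModel] = []
    skipped: dict[str, str] = {}
    n_folds = 10 if penalty_strategy == "cv10" else 1
    grid = alphas if penalty_strategy == "cv10" else alphas[:1]
    for drug in train.ic50.index:
        y = train.ic50.loc[drug]
        n_ok = int(y.notna().sum())
        if n_ok < 10:
            skipped[drug] = f"only {n_ok} non-missing IC50 values (<10)"
            logger.warning("skipping %s: %s", drug, skipped[drug])
            continue
        models.append(_fit_one_drug(drug, y, tr_expr, grid, n_folds, seed))
    return RidgeImputation(models=models, patient_expr=pt_expr, skipped=skipped)


def predict_pic50(models, patient_expr: ExpressionMatrix | None = None) -> pd.DataFrame:
    """drugs x patients predicted pIC50 matrix. When ``models`` is a
    RidgeImputation and no matrix is given, its homogenized patient matrix
    is used."""
    if isinstance(models, RidgeImputation):
        if patient_expr is None:
            patient_expr = models.patient_expr
        models = models.models
    if patient_expr is None:
        raise ValueError("patient expression matrix required")
    rows = [m.predict(patient_expr) for m in models]
    return pd.DataFrame(rows)


def delta_pic50_test(pic50_row: pd.Series, hrd_status: pd.Series, center: str = "mean") -> dict:
    """Per-drug HRD association: delta = center(proficient) -
    center(deficient); two-sided Wilcoxon rank-sum p. One empty group
    flags the drug untestable (NaN statistics)."""
    status = hrd_status.reindex(pic50_row.index)
    prof = pic50_row[status == "HR_proficient"].dropna()
    defi = pic50_row[status == "HR_deficient"].dropna()
    if len(prof) == 0 or len(defi) == 0:
        return {"delta_pic50": np.nan, "p_value": np.nan, "testable": False}
    agg = np.mean if center == "mean" else np.median
    delta = float(agg(prof) - agg(defi))
    res = wilcoxon_rank_sum(prof.to_numpy(), defi.to_numpy())
    return {"delta_pic50": delta, "p_value": res.p_value, "testable": True}


def delta_pic50_table(pic50: pd.DataFrame, hrd_status: pd.Series, center: str = "mean") -> pd.DataFrame:
    """Apply delta_pic50_test to every drug, BH FDR across the tested
    family (untestable drugs carry NaN FDR)."""
    rows = []
    for drug in pic50.index:
        r = delta_pic50_test(pic50.loc[drug], hrd_status, center=center)
        r["drug_id"] = drug
        rows.append(r)
    df = pd.DataFrame(rows).set_index("drug_id")
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df[["delta_pic50", "p_value", "fdr", "testable"]]
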