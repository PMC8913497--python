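"""Shared statistical kernel: rank tests, correlation, multiple testing,
survival regression and ROC.

Conventions used throughout the pipeline:

* all tests are two-sided with significance at p < 0.05 unless a caller
  overrides the threshold;
* the Wilcoxon rank-sum test is exact (full enumeration of the
  Mann-Whitney null) when both groups are small and untied, otherwise a
  normal approximation with tie and continuity corrections is used;
* Spearman's rho uses midranks for ties; its p-value is exact (full
  permutation) for n <= 9 untied observations and a t-approximation
  otherwise;
* multiple testing is Benjamini-Hochberg step-up throughout;
* Cox proportional-hazards fits use Efron's tie handling.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankTestResult",
    "CorrelationResult",
    "CoxFit",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "spearman",
    "bh_fdr",
    "cox_fit",
    "median_split",
    "roc_auc",
]

EXACT_WILCOXON_MAX_N = 20
EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    method: str


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit summary.

    Hazard ratios are exp(estimate); confidence intervals are
    exp(estimate +/- 1.96 * SE).
    """

    covariates: list[str]
    log_hr: np.ndarray
    se: np.ndarray
    n: int
    n_events: int
    warnings: list[str] = field(default_factory=list)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.log_hr)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.log_hr - 1.96 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.log_hr + 1.96 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        z = self.log_hr / self.se
        return 2.0 * sps.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "log_hr": self.log_hr,
                "se": self.se,
                "hr": self.hazard_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p_value": self.p_values,
            }
        )


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> RankTestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when n_x + n_y <= 20 and there are no ties across the pooled
    sample; otherwise normal approximation with tie correction and
    continuity correction. All values tied across both groups gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankTestResult(statistic=float(x.size * y.size / 2.0), p_value=1.0, method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if (x.size + y.size) <= EXACT_WILCOXON_MAX_N and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return RankTestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method=method)


def kruskal_wallis(*groups) -> RankTestResult:
    """Kruskal-Wallis rank test for >2 groups (thin rank-machinery extension)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    res = sps.kruskal(*groups)
    return RankTestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method="kruskal")


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    # Enumerate all permutations of y's ranks; two-sided p on |rho|.
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    denom = n * (n**2 - 1)
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry):
        d2 = np.sum((rx - np.asarray(perm)) ** 2)
        rho = 1.0 - 6.0 * d2 / denom
        if abs(rho) >= target:
            count += 1
        total += 1
    return count / total


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midrank ties.

    p-value by full permutation enumeration for n <= 9 untied data,
    t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 observations")
    rho, p_approx = sps.spearmanr(x, y)
    untied = np.unique(x).size == n and np.unique(y).size == n
    if n <= EXACT_SPEARMAN_MAX_N and untied and np.isfinite(rho):
        p = _spearman_exact_p(x, y, float(rho))
        method = "exact"
    else:
        p = float(p_approx)
        method = "t-approx"
    return CorrelationResult(rho=float(rho), p_value=p, n=n, method=method)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values. NaN inputs yield NaN outputs."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def cox_fit(time, event, covariates: pd.DataFrame | np.ndarray, names=None) -> CoxFit:
    """Cox proportional-hazards regression (partial likelihood, Efron ties).

    Flags — rather than fails on — apparent monotone-likelihood /
    separation problems, returning the estimates with a warning string.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceWarning

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if isinstance(covariates, pd.DataFrame):
        X = covariates.reset_index(drop=True)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != time.size:
            X = X.T
        cols = names if names is not None else [f"x{i}" for i in range(X.shape[1])]
        X = pd.DataFrame(X, columns=cols)
    for col in X.columns:
        if np.unique(X[col].to_numpy()).size < 2:
            raise ValueError(f"covariate {col!r} is constant")
    df = X.copy()
    df["__time"] = time
    df["__event"] = event
    fitter = CoxPHFitter()
    warns: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        fitter.fit(df, duration_col="__time", event_col="__event")
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                warns.append(str(w.message))
    est = fitter.params_.to_numpy()
    se = fitter.standard_errors_.to_numpy()
    if np.any(np.abs(est) > 10) or np.any(se > 100):
        warns.append("possible monotone likelihood / separation: extreme estimates")
    return CoxFit(
        covariates=list(X.columns),
        log_hr=est,
        se=se,
        n=int(time.size),
        n_events=int(event.sum()),
        warnings=warns,
    )


def median_split(values) -> np.ndarray:
    """Binary labels: True for strictly above the median ("sensitive" in the
    failure-free-interval convention); values tied with the median fall in
    the not-above group."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    med = float(np.median(v))
    labels = v > med
    if not labels.any():
        warnings.warn("median_split: no value strictly above the median", stacklevel=2)
    return labels


def roc_auc(scores, labels) -> float:
    """ROC AUC as the Mann-Whitney U probability (midrank tie handling)."""
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("need both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
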