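"""Self-evaluation harness: runs each pipeline stage against the
planted-truth simulator and measures how well the truth is recovered.

Every routine here generates its own inputs from a seed, executes the
corresponding analysis stage through the public module surfaces, and
returns the measured quantity — recovery rates, held-out performance,
null-calibration statistics. The acceptance script and the acceptance
test suite both call these functions, so the numbers they report are
always recomputed from scratch.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import connectivity as conn
from . import drug_response as dr
from . import signature as sig
from . import synthetic as syn
from .stats import cox_fit, roc_auc, spearman, wilcoxon_rank_sum

__all__ = [
    "confusion_worked_example",
    "signature_stage",
    "hrd_score_holdout_auc",
    "ridge_holdout_r2",
    "delta_pic50_flagging",
    "pic50_survival_risk",
    "cox_recovery",
    "connectivity_planted",
    "connectivity_null_calibration",
    "nb_wald_null_calibration",
    "rank_test_type1",
]


def confusion_worked_example(
    n_high_score: int = 46,
    n_high_deficient: int = 42,
    n_low_score: int = 37,
    n_low_proficient: int = 31,
) -> dict:
    """PPV/NPV of the HRD-score classifier at threshold 0.5, from the
    reported confusion counts of the TCGA TNBC cohort (42/46 deficient
    above 0.5, 31/37 proficient at or below 0.5)."""
    scores = np.concatenate([
        np.full(n_high_score, 0.9), np.full(n_low_score, 0.1),
    ])
    truth = np.concatenate([
        np.ones(n_high_deficient), np.zeros(n_high_score - n_high_deficient),
        np.zeros(n_low_proficient), np.ones(n_low_score - n_low_proficient),
    ])
    predicted = scores > 0.5
    ppv = 100.0 * float((truth[predicted] == 1).mean())
    npv = 100.0 * float((truth[~predicted] == 0).mean())
    return {"ppv_pct": ppv, "npv_pct": npv,
            "n_positive": n_high_score, "n_negative": n_low_score}


def _status_series(cohort: syn.SyntheticCohort) -> pd.Series:
    g = cohort.genomic_hrd
    return pd.Series(g["status"].to_numpy(), index=g["sample_id"])


def signature_stage(seed: int, config: syn.SimulationConfig | None = None) -> dict:
    """DE -> threshold selection -> purity filter on the default cohort;
    measures recovery of planted signature genes, contamination of the
    selected set, and removal of planted purity-confounded genes."""
    cfg = config or syn.SimulationConfig(seed=seed)
    cohort = syn.generate_cohort(cfg)
    status = _status_series(cohort)
    de = sig.nb_wald_test(cohort.counts, status.reindex(cohort.counts.sample_ids))
    up, down = sig.select_signature(de)
    log2_expr = dr.log2_transform(cohort.counts)
    hrd_sig = sig.purity_filter((up, down), log2_expr, cohort.purity)

    truth_up = set(cohort.truth.up_genes)
    truth_down = set(cohort.truth.down_genes)
    n_truth = len(truth_up) + len(truth_down)
    hit = len(truth_up & set(hrd_sig.up_genes)) + len(truth_down & set(hrd_sig.down_genes))
    n_sel = len(hrd_sig.up_genes) + len(hrd_sig.down_genes)
    contam = (len(set(hrd_sig.up_genes) - truth_up) + len(set(hrd_sig.down_genes) - truth_down))

    pf = sig.purity_filter((list(cohort.truth.purity_genes), []), log2_expr, cohort.purity)
    purity_removed = 1.0 - len(pf.up_genes) / len(cohort.truth.purity_genes)
    return {
        "recovery": hit / n_truth,
        "contamination": contam / max(n_sel, 1),
        "purity_removal": purity_removed,
        "n_truth": n_truth,
        "n_selected": n_sel,
        "signature": hrd_sig,
        "cohort": cohort,
        "status": status,
    }


def hrd_score_holdout_auc(
    seed: int,
    n_eval: int = 200,
    n_refits: int = 10,
    stage: dict | None = None,
) -> dict:
    """Fit the lasso HRD score on the default cohort's recovered signature
    genes and evaluate the AUC against genomic status on an independent
    cohort drawn from the same simulated population."""
    stage = stage or signature_stage(seed)
    cohort, status, hrd_sig = stage["cohort"], stage["status"], stage["signature"]
    genes = hrd_sig.genes
    log2_expr = dr.log2_transform(cohort.counts)
    model = sig.fit_hrd_score(
        log2_expr, status.reindex(log2_expr.sample_ids), genes=genes,
        n_refits=n_refits, seed=seed,
    )
    eval_cfg = dataclasses.replace(
        syn.SimulationConfig(seed=seed), seed=seed + 10_000, population_seed=seed,
        n_patients=n_eval,
    )
    eval_cohort = syn.generate_cohort(eval_cfg)
    eval_status = _status_series(eval_cohort)
    scores = sig.predict_hrd_score(model, dr.log2_transform(eval_cohort.counts))
    auc = roc_auc(scores.to_numpy(), (eval_status.reindex(scores.index) == "HR_deficient"))
    return {"auc": auc, "n_eval": n_eval, "lambda": model.lambda_, "model": model}


def ridge_holdout_r2(seed: int, n_holdout: int = 50) -> dict:
    """Train the ridge imputation on part of the default cell-line panel
    and measure held-out R^2 on the remaining lines, per planted drug."""
    cfg = syn.SimulationConfig(seed=seed)
    panel = syn.generate_cell_line_panel(cfg)
    lines = panel.expression.sample_ids
    tr, te = lines[:-n_holdout], lines[-n_holdout:]
    train = syn.PharmacoTrainingSet(
        expression=panel.expression.subset_samples(tr),
        ic50=panel.ic50[tr],
        batch_labels=panel.batch_labels[tr],
    )
    imp = dr.fit_ridge_models(train, panel.expression.subset_samples(te), seed=seed)
    pred = dr.predict_pic50(imp)
    cohort_truth = syn.generate_cohort(cfg).truth
    r2 = {}
    for drug in cohort_truth.hrd_sensitive_drugs:
        y = panel.ic50.loc[drug, te]
        ok = y.notna()
        resid = y[ok] - pred.loc[drug][y.index[ok]]
        r2[drug] = float(1.0 - (resid**2).sum() / ((y[ok] - y[ok].mean()) ** 2).sum())
    return {"r2_by_drug": r2, "min_r2": min(r2.values()), "mean_r2": float(np.mean(list(r2.values()))),
            "n_holdout": n_holdout}


def delta_pic50_flagging(seed: int, fdr_max: float = 0.05, stage: dict | None = None) -> dict:
    """Impute pIC50 for the default cohort and check that planted
    HRD-sensitive drugs are flagged (delta > 0, FDR below threshold)."""
    cfg = syn.SimulationConfig(seed=seed)
    panel = syn.generate_cell_line_panel(cfg)
    stage = stage or signature_stage(seed)
    cohort, status = stage["cohort"], stage["status"]
    imp = dr.fit_ridge_models(panel, cohort.counts, seed=seed)
    pic50 = dr.predict_pic50(imp)
    delta = dr.delta_pic50_table(pic50, status)
    sens = cohort.truth.hrd_sensitive_drugs
    flagged = [
        d for d in sens
        if delta.loc[d, "delta_pic50"] > 0 and delta.loc[d, "fdr"] < fdr_max
    ]
    null_drugs = [d for d in delta.index if d not in sens]
    return {
        "flagged_fraction": len(flagged) / len(sens),
        "n_sensitive": len(sens),
        "delta_table": delta,
        "max_abs_null_delta": float(delta.loc[null_drugs, "delta_pic50"].abs().max()),
        "min_planted_delta": float(delta.loc[sens, "delta_pic50"].min()),
        "pic50": pic50,
        "cohort": cohort,
    }


def pic50_survival_risk(seed: int, flagging: dict | None = None) -> dict:
    """Cox regression of cohort survival on a planted HRD-sensitive drug's
    imputed pIC50: predicted resistance should be a risk factor (HR > 1
    with the CI excluding 1)."""
    flagging = flagging or delta_pic50_flagging(seed)
    cohort, pic50 = flagging["cohort"], flagging["pic50"]
    drug = cohort.truth.hrd_sensitive_drugs[0]
    x = pic50.loc[drug].reindex(cohort.survival_time.index)
    fit = cox_fit(
        cohort.survival_time.to_numpy(), cohort.survival_event.to_numpy(),
        x.to_numpy(), names=[drug],
    )
    return {
        "drug": drug,
        "hr": float(fit.hazard_ratios[0]),
        "ci_lower": float(fit.ci_lower[0]),
        "ci_upper": float(fit.ci_upper[0]),
        "n": fit.n,
        "n_events": fit.n_events,
    }


def cox_recovery(seed: int, n: int = 500, loghr: float = 0.7) -> dict:
    """Exponential survival with planted log-hazard slope; Cox estimate."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    hazard = 0.1 * np.exp(loghr * x)
    t_event = rng.exponential(1.0 / hazard)
    censor = rng.uniform(5.0, 30.0, n)
    fit = cox_fit(np.minimum(t_event, censor), (t_event <= censor).astype(int), x)
    return {"loghr_est": float(fit.log_hr[0]), "loghr_true": loghr, "n": n,
            "n_events": fit.n_events}


def connectivity_planted(seed: int, n_perm: int = 1000, stage: dict | None = None) -> dict:
    """Score planted concordant (+1) and reversing (-1) perturbation
    profiles against the planted signature."""
    cfg = syn.SimulationConfig(seed=seed)
    cohort = (stage or {}).get("cohort") or syn.generate_cohort(cfg)
    up, down = cohort.truth.up_genes, cohort.truth.down_genes
    sens = cohort.truth.hrd_sensitive_drugs
    concord = {d: (1.0 if d in sens else 0.0) for d in cfg.drug_ids()}
    concord[cfg.drug_ids()[-1]] = -1.0  # one planted reverser
    profiles = syn.generate_perturbation_profiles(cfg, concordance=concord)
    table = conn.score_profiles(profiles, up, down, n_perm=n_perm, seed=seed).set_index("drug_id")
    pos_ok = [d for d in sens
              if table.loc[d, "connectivity_score"] > 0 and table.loc[d, "fdr"] < 0.05]
    reverser = cfg.drug_ids()[-1]
    return {
        "concordant_flagged_fraction": len(pos_ok) / len(sens),
        "n_concordant": len(sens),
        "reverser_cs": float(table.loc[reverser, "connectivity_score"]),
        "table": table,
    }


def connectivity_null_calibration(
    seed: int, n_draws: int = 2000, n_perm: int = 1000,
    n_genes: int = 1000, set_size: int = 30,
) -> dict:
    """Permutation p-values of random gene sets on an exchangeable ranking
    should be uniform; returns the KS test against Uniform(0,1)."""
    rng = np.random.default_rng(seed)
    ranking = [f"g{i}" for i in range(n_genes)]
    pvals = np.empty(n_draws)
    for i in range(n_draws):
        pos = np.sort(rng.choice(n_genes, size=set_size, replace=False))
        es = conn._es_from_positions(pos.astype(float), n_genes, set_size)
        null = conn._null_es_sample(n_genes, set_size, n_perm,
                                    np.random.default_rng(rng.integers(2**31 - 1)))
        pvals[i] = conn.permutation_p(es, null)
    ks = sps.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "n_draws": n_draws, "pvals": pvals}


def nb_wald_null_calibration(
    seed: int, n_genes: int = 1000, n_per_group: int = 100, dispersion: float = 0.1,
) -> dict:
    """NB Wald p-values under a null two-group comparison should be
    uniform; returns the KS test against Uniform(0,1)."""
    from .io_formats import ExpressionMatrix, Unit

    rng = np.random.default_rng(seed)
    base = np.clip(rng.lognormal(np.log(100.0), 1.0, n_genes), 5.0, None)
    n = 2 * n_per_group
    r = 1.0 / dispersion
    mu = np.repeat(base[:, None], n, axis=1)
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    labels = ["a"] * n_per_group + ["b"] * n_per_group
    matrix = ExpressionMatrix(
        [f"g{i}" for i in range(n_genes)], [f"s{i}" for i in range(n)], counts, Unit.counts
    )
    de = sig.nb_wald_test(matrix, labels)
    p = de["p_value"].dropna().to_numpy()
    ks = sps.kstest(p, "uniform")
    return {"ks_p": float(ks.pvalue), "n_genes_tested": int(p.size), "pvals": p}


def rank_test_type1(seed: int, n_reps: int = 200, n: int = 25, alpha: float = 0.05) -> dict:
    """Empirical type-I error of the Wilcoxon rank-sum and Spearman tests
    on exchangeable Gaussian data."""
    rng = np.random.default_rng(seed)
    wil = 0
    spe = 0
    for _ in range(n_reps):
        x, y = rng.normal(size=n), rng.normal(size=n)
        if wilcoxon_rank_sum(x, y).p_value < alpha:
            wil += 1
        a, b = rng.normal(size=30), rng.normal(size=30)
        if spearman(a, b).p_value < alpha:
            spe += 1
    return {
        "wilcoxon_rate": wil / n_reps,
        "spearman_rate": spe / n_reps,
        "n_reps": n_reps,
        "alpha": alpha,
        "band_2sd": 2.0 * float(np.sqrt(alpha * (1 - alpha) / n_reps)),
    }
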