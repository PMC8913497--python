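#!/usr/bin/env python
"""Single-sample enrichment (DRscore / hallmark activities) and survival
regression on imputed drug sensitivity.

GSVA-style scores of per-drug response/resistance signatures and
hallmark-style sets are tested against HRD status (Wilcoxon) and against
each other (Spearman, BH FDR); Cox proportional-hazards models relate
each drug's imputed pIC50 to survival. Writes
results/drscore_hrd_tests.tsv, results/drug_hallmark_correlations.tsv,
results/survival_cox.tsv.
"""

from pathlib import Path

import pandas as pd

from hrd_pharmaco import drug_response as dr
from hrd_pharmaco import enrichment as enr
from hrd_pharmaco.stats import cox_fit
from hrd_pharmaco.synthetic import (
    SimulationConfig,
    generate_cell_line_panel,
    generate_cohort,
    generate_gene_sets,
)

SEED = 0
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    cohort = generate_cohort(cfg)
    status = pd.Series(
        cohort.genomic_hrd["status"].to_numpy(), index=cohort.genomic_hrd["sample_id"]
    )
    sets = generate_gene_sets(cfg)
    log2_expr = dr.log2_transform(cohort.counts)

    drscores = enr.gsva_scores(log2_expr, sets["drug_signatures"])
    hallmarks = enr.gsva_scores(log2_expr, sets["hallmarks"])
    dr_tests = enr.drscore_hrd_table(drscores, status)
    corr = enr.drug_hallmark_correlations(drscores.scores, hallmarks.scores)

    panel = generate_cell_line_panel(cfg)
    pic50 = dr.predict_pic50(dr.fit_ridge_models(panel, cohort.counts, seed=SEED))
    rows = []
    for drug in pic50.index:
        fit = cox_fit(cohort.survival_time.to_numpy(), cohort.survival_event.to_numpy(),
                      pic50.loc[drug].to_numpy(), names=[drug])
        s = fit.summary().iloc[0]
        rows.append((drug, s.log_hr, s.hr, s.ci_lower, s.ci_upper, s.p_value))
    surv = pd.DataFrame(rows, columns=["drug_id", "log_hr", "hr", "ci_lower",
                                       "ci_upper", "p_value"])

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    dr_tests.to_csv(out / "drscore_hrd_tests.tsv", sep="\t")
    corr.to_csv(out / "drug_hallmark_correlations.tsv", sep="\t", index=False)
    surv.to_csv(out / "survival_cox.tsv", sep="\t", index=False)

    planted_resp = [f"{d}_RESPONSE" for d in cohort.truth.hrd_sensitive_drugs]
    hits = dr_tests.loc[planted_resp]
    print(dr_tests[dr_tests["fdr"] < 0.05].round(4).to_string())
    print(
        f"\nFinding: {(hits['fdr'] < 0.05).sum()} of {len(hits)} planted HRD-sensitive "
        "drugs' response signatures have DRscores significantly higher in HR-deficient "
        f"patients (all directions positive: {(hits['direction'] > 0).all()})."
    )
    sens = surv[surv['drug_id'].isin(cohort.truth.hrd_sensitive_drugs)]
    print(
        "Finding: higher imputed pIC50 (resistance) of planted HRD-sensitive drugs "
        f"is a risk factor (HR > 1, CI excluding 1) for {((sens['ci_lower'] > 1)).sum()} "
        f"of {len(sens)} drugs — the planted hazard falls along the HRD axis, so "
        "predicted resistance tracks shorter survival."
    )


if __name__ == "__main__":
    main()
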