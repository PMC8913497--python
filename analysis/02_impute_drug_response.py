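#!/usr/bin/env python
"""Impute patient drug sensitivity from the cell-line panel and test its
HRD association.

Ridge models per drug (penalty by 10-fold CV) are trained on cell-line
log2 expression after the shared filter -> log2 -> cohort batch
adjustment, then applied to the patient cohort; delta-pIC50 =
mean(HR-proficient) - mean(HR-deficient), with a two-sided Wilcoxon
rank-sum p and BH FDR across drugs. Writes results/delta_pic50.tsv.
"""

from pathlib import Path

import pandas as pd

from hrd_pharmaco import drug_response as dr
from hrd_pharmaco.synthetic import (
    SimulationConfig,
    generate_cell_line_panel,
    generate_cohort,
)

SEED = 0
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    cohort = generate_cohort(cfg)
    panel = generate_cell_line_panel(cfg)
    status = pd.Series(
        cohort.genomic_hrd["status"].to_numpy(), index=cohort.genomic_hrd["sample_id"]
    )

    imputation = dr.fit_ridge_models(panel, cohort.counts, seed=SEED)
    pic50 = dr.predict_pic50(imputation)
    delta = dr.delta_pic50_table(pic50, status)
    delta["planted_sensitive"] = [
        d in cohort.truth.hrd_sensitive_drugs for d in delta.index
    ]

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    delta.to_csv(out / "delta_pic50.tsv", sep="\t")

    flagged = delta[(delta["delta_pic50"] > 0) & (delta["fdr"] < 0.05)]
    planted = delta[delta["planted_sensitive"]]
    print(delta.round(4).to_string())
    print(
        f"\nFinding: {len(planted[planted.index.isin(flagged.index)])} of "
        f"{len(planted)} planted HRD-sensitive drugs are flagged (delta-pIC50 > 0, "
        f"FDR < 0.05); their smallest delta is {planted['delta_pic50'].min():.2f}, "
        "while null drugs' deltas stay near zero "
        f"(max |delta| = {delta.loc[~delta['planted_sensitive'], 'delta_pic50'].abs().max():.3f})."
    )


if __name__ == "__main__":
    main()
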