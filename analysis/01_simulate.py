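#!/usr/bin/env python
"""Generate the synthetic study population and write the fixture set.

The simulator plants a latent HRD axis: 26 up / 40 down signature genes
(fold change 5 in HR-deficient patients), 30 purity-confounded genes, a
scar score ~95% concordant with the latent label at the >=42 rule, six
HRD-sensitive drugs (log-IC50 slope -1 on the axis) among 20, and
exponential survival with log-hazard 0.7 per axis unit.

Full fixture files (GCT/GMT/TSV) go to scratch/fixtures/; a small cohort
summary table goes to results/.
"""

from pathlib import Path

import pandas as pd

from hrd_pharmaco.synthetic import SimulationConfig, generate_cohort, write_fixture_set

SEED = 0
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    fixtures = ROOT / "scratch" / "fixtures"
    paths = write_fixture_set(cfg, fixtures)
    cohort = generate_cohort(cfg)

    status = cohort.genomic_hrd["status"]
    summary = pd.DataFrame(
        {
            "quantity": [
                "n_patients", "n_genes", "n_drugs", "hr_deficient", "hr_proficient",
                "brca_carriers", "median_scar_deficient", "median_scar_proficient",
                "survival_events",
            ],
            "value": [
                cfg.n_patients, cfg.n_genes, cfg.n_drugs,
                int((status == "HR_deficient").sum()),
                int((status == "HR_proficient").sum()),
                int((cohort.genomic_hrd[["brca1_deleterious", "brca2_deleterious"]]
                     .any(axis=1)).sum()),
                float(cohort.genomic_hrd.loc[status == "HR_deficient", "scar_score"].median()),
                float(cohort.genomic_hrd.loc[status == "HR_proficient", "scar_score"].median()),
                int(cohort.survival_event.sum()),
            ],
        }
    )
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)

    print(f"wrote {len(paths)} fixture files to {fixtures}")
    print(summary.to_string(index=False))
    print(
        "\nFinding: the genomic HRD rule (scar >= 42 or deleterious BRCA1/2) calls "
        f"{(status == 'HR_deficient').mean():.0%} of patients HR-deficient, close to the "
        f"planted fraction {cfg.hrd_fraction:.0%}."
    )


if __name__ == "__main__":
    main()
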