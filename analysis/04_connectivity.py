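#!/usr/bin/env python
"""Connectivity-map analysis of the planted HRD signature against
drug-perturbed profiles, drug clustering, and anticorrelated pairs.

Each drug profile is scored with the unweighted KS running sum for the
signature's up and down sets; NES normalizes ES against 1,000 random
size-matched gene sets, CS = NES_up - NES_down. Drugs are then clustered
by consensus (average linkage over 100 subsample resamples) on their
pairwise perturbation similarity, and negatively correlated imputed-
response drug pairs (R <= -0.3, FDR <= 0.01) are listed. Writes
results/connectivity.tsv, results/drug_clusters.tsv,
results/anticorrelated_pairs.tsv.
"""

from pathlib import Path

import pandas as pd

from hrd_pharmaco import connectivity as conn
from hrd_pharmaco import drug_response as dr
from hrd_pharmaco.synthetic import (
    SimulationConfig,
    generate_cell_line_panel,
    generate_cohort,
    generate_perturbation_profiles,
)

SEED = 0
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    cohort = generate_cohort(cfg)
    # concordance +1 for planted HRD-sensitive drugs, -1 for the last drug
    concord = {d: (1.0 if d in cohort.truth.hrd_sensitive_drugs else 0.0)
               for d in cfg.drug_ids()}
    concord[cfg.drug_ids()[-1]] = -1.0
    profiles = generate_perturbation_profiles(cfg, concordance=concord)

    table = conn.score_profiles(
        profiles, cohort.truth.up_genes, cohort.truth.down_genes, n_perm=1000, seed=SEED
    )
    simmat = conn.similarity_matrix(profiles, top_n=150, seed=SEED)
    labels, consensus = conn.consensus_cluster(simmat, k=5, seed=SEED)

    panel = generate_cell_line_panel(cfg)
    imputation = dr.fit_ridge_models(panel, cohort.counts, seed=SEED)
    pic50 = dr.predict_pic50(imputation)
    pairs = conn.anticorrelated_pairs(pic50)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "connectivity.tsv", sep="\t", index=False)
    labels.to_frame().to_csv(out / "drug_clusters.tsv", sep="\t")
    pairs.to_csv(out / "anticorrelated_pairs.tsv", sep="\t", index=False)

    t = table.set_index("drug_id")
    pos = [d for d in cohort.truth.hrd_sensitive_drugs
           if t.loc[d, "connectivity_score"] > 0 and t.loc[d, "fdr"] < 0.05]
    rev = cfg.drug_ids()[-1]
    print(t[["connectivity_score", "p_value", "fdr"]].round(3).to_string())
    print(
        f"\nFinding: all {len(pos)}/{len(cohort.truth.hrd_sensitive_drugs)} concordant "
        "drugs score CS > 0 at FDR < 0.05 (perturbation mimics the HRD signature), "
        f"while the planted reverser {rev} scores CS = "
        f"{t.loc[rev, 'connectivity_score']:.2f} (it pushes the signature the other way)."
    )
    print(f"consensus clustering at k=5 groups: {labels.value_counts().to_dict()}")
    print(f"anticorrelated response pairs kept (R <= -0.3, FDR <= 0.01): {len(pairs)}")


if __name__ == "__main__":
    main()
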