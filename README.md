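# hrd-pharmaco

HRD-conditioned pharmacogenomics for triple-negative breast cancer
(TNBC), as a tested, reusable pipeline.

TNBC lacks targeted therapies, but homologous-recombination repair
deficiency (HRD) — from BRCA1/2 loss or genomic scarring — marks tumors
that respond to DNA-damaging drugs and PARP inhibitors. This package
implements the full analysis chain a pharmacogenomics group would run to
exploit that:

1. **Genomic HRD call** — HR-deficient iff scar score ≥ 42 or a
   deleterious tumor BRCA1/2 mutation.
2. **Drug-sensitivity imputation** — per-drug ridge regression from
   cell-line expression + log-IC50 panels to patient pIC50, after a
   shared filter → log2 → empirical-Bayes batch-adjustment chain;
   ΔpIC50 = mean(HR-proficient) − mean(HR-deficient) with Wilcoxon p and
   BH FDR (Δ > 0 ⇒ more potent in HR-deficient tumors).
3. **HRD transcriptomic signature** — NB Wald differential expression
   (FDR ≤ 0.01, FC ≥ 3 or ≤ 1/3), a tumor-purity filter (drop genes with
   Spearman R < 0, p ≤ 0.05 vs purity), and a lasso-logistic HRD score
   with 10-fold CV over the λ path and 300 stability refits.
4. **Connectivity-map analysis** — unweighted KS enrichment of the
   signature's up/down sets in drug-perturbed ranked profiles;
   NES = ES / mean(|null ES| of matching sign) over 1,000 random
   size-matched sets; **CS = NES_up − NES_down** (CS > 0: the drug mimics
   the HRD expression state; CS < 0: it reverses it); drug clustering by
   consensus over perturbation similarity; anticorrelated response pairs
   (R ≤ −0.3, FDR ≤ 0.01).
5. **Single-sample enrichment** — GSVA-style drug-response scores
   (DRscore) and hallmark activities, tested against HRD status and each
   other.
6. **Survival** — Cox proportional hazards (Efron ties) of imputed pIC50
   on survival.

Real cohorts are not required: a first-class synthetic-data module plants
a known HRD axis (signature genes, purity confounders, scar scores, drug
slopes, survival hazards) so every stage is testable against ground
truth. Real-data formats (GCT 1.2, GMT, clinical/mutation TSV) are read
and written throughout.

## Worked example

Run the numbered analysis scripts (or `hrd-pharmaco run-full --synthetic`)
on the default simulated study — 80 TNBC patients, 200 cell lines, 2,000
genes, 20 drugs of which six are planted HRD-sensitive:

```bash
python analysis/01_simulate.py
python analysis/02_impute_drug_response.py
python analysis/03_derive_signature.py
python analysis/04_connectivity.py
python analysis/05_enrichment_survival.py
```

Selected output (seed 0):

```
Finding: 6 of 6 planted HRD-sensitive drugs are flagged (delta-pIC50 > 0,
FDR < 0.05); their smallest delta is 1.35, while null drugs' deltas stay
near zero (max |delta| = 0.018).

signature: 26 up / 40 down genes; recovery of planted genes 100.0%
lasso HRD score: lambda* = 0.0430745, 9 genes selected, training AUC 0.997
against genomic status (300 stability refits)

Finding: all 6/6 concordant drugs score CS > 0 at FDR < 0.05 (perturbation
mimics the HRD signature), while the planted reverser DRUG020 scores
CS = -12.09 (it pushes the signature the other way).

Finding: higher imputed pIC50 (resistance) of planted HRD-sensitive drugs
is a risk factor (HR > 1, CI excluding 1) for 6 of 6 drugs.
```

Reading the numbers: a ΔpIC50 of 1.35 log units means HR-deficient
patients are predicted markedly more sensitive to the planted drugs; the
66-gene signature is recovered exactly; the lasso keeps 9 genes at
λ* ≈ 0.043 and separates genomic HRD almost perfectly; connectivity
scores sort mimickers (CS > 0) from reversers (CS < 0), the dichotomy
that distinguishes drugs which phenocopy HRD from drugs that undo it;
and predicted resistance transfers to shorter survival, as a Cox hazard
ratio above 1.

Each script writes its tables under `results/`; every pipeline stage also
has a CLI subcommand (`hrd-pharmaco synth|hrd-call|impute-pic50|
derive-signature|score-hrd|cmap-score|cmap-cluster|ssenrich|survival|
run-full`) operating on GCT/GMT/TSV files with shared
`--config --seed --out-dir --log-level` flags.

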