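# Methods

This package re-implements, end to end, an HRD-conditioned pharmacogenomic
analysis for triple-negative breast cancer (TNBC): imputing patient drug
sensitivity from cell-line panels, deriving a transcriptomic signature of
homologous-recombination deficiency (HRD), scoring that signature against
drug-perturbed expression profiles, and testing the downstream clinical
associations. Because the original cohorts (TCGA, GEO, METABRIC, GDSC,
LINCS) are not shipped, every stage runs against a synthetic-data
generator that plants a known HRD axis, so each method's output can be
compared with a ground truth.

## The genomic HRD call

A patient is HR-deficient when the genomic scar score (the LOH + LST +
ntAI index) is at least 42 — the comparison is inclusive — or when the
tumor carries a deleterious BRCA1/2 mutation; everyone else is
HR-proficient. The threshold is configurable and defaults to 42.
Deleteriousness is a pluggable rule; the default counts truncating
variants (nonsense, frameshift, splice-site) and anything pre-annotated
deleterious, and treats unknown classification strings as non-deleterious
with a warning. A missing scar score with no mutation evidence propagates
as a missing status; we do not impute.

## Drug-sensitivity imputation

The training panel is cell-line expression plus per-drug log-IC50 values
(log scale throughout); each drug needs at least 10 non-missing values or
it is skipped with a logged reason. Training and patient expression are
homogenized jointly: genes intersected, genes with zero counts in more
than five samples removed (strict "more than"), log2(x + 1) transform
(pseudocount configurable), then a parametric empirical-Bayes
location/scale batch adjustment with cohort (train vs test) as the batch
variable. The batch adjustment standardizes each gene, shrinks per-batch
means and variances toward normal / inverse-gamma priors fitted across
genes, removes them, and restores the per-gene grand mean; a single batch
is an exact identity and a one-sample batch is an error.

One ridge regression per drug maps per-gene-standardized log2 expression
to log-IC50; the penalty is chosen by 10-fold cross-validation minimizing
mean squared error over a log-spaced grid (17 points, 1e-2 to 1e6) with a
fixed fold seed. Predicted pIC50 is lower in more sensitive patients. The
HRD association per drug is

    delta_pIC50 = mean(HR-proficient) - mean(HR-deficient)

with a two-sided Wilcoxon rank-sum p-value and Benjamini-Hochberg FDR
across drugs: delta > 0 means the drug is more potent in HR-deficient
tumors. The mean is the default aggregator (median by config).

A caveat we document rather than hide: imputed pIC50 is a deterministic
function of expression, so for a drug whose IC50 is truly independent of
the HRD axis, any noise-driven coefficient loading on axis-correlated
genes still produces a small systematic group shift. The rank test is
scale-invariant and will flag such drugs at far above the nominal rate
even though their effect sizes are negligible (here ~1% of the planted
effects). Association tests on imputed phenotypes inherit this inflation
in general; consumers should read delta magnitudes together with FDRs.

## The HRD transcriptomic signature

Differential expression between genomic HRD groups uses the DESeq2 model
(negative-binomial GLM, median-of-ratios size factors, trend-shrunk
gene-wise dispersions, Wald test), computed through pydeseq2 with Cook's
outlier refitting and independent filtering disabled so that thresholds,
not estimator extras, determine membership. FDR is recomputed as plain BH
over all tested genes. Signature membership requires FDR <= 0.01 and fold
change >= 3 (up) or <= 1/3 (down), on the raw (unshrunken) log2 fold
change. Candidates whose expression correlates negatively with tumor
purity (Spearman R < 0 and p <= 0.05 — one-sided on the sign) are then
removed, because stromal admixture can mimic tumor-intrinsic HRD effects;
removals are logged with their statistics, and a constant purity vector
skips the filter with a warning.

The transcriptomic HRD score is a lasso-logistic regression of genomic
status on the signature genes (per-gene standardized). The lambda grid is
100 points log-spaced from lambda_max (the smallest penalty zeroing every
coefficient) down to 1e-4 * lambda_max; lambda* minimizes 10-fold
cross-validated binomial deviance (misclassification by config — the
"error rate" notion is not uniquely defined, so both are exposed).
Stability is assessed by refitting with freshly randomized fold
assignments 300 times and recording per-gene selection frequencies; the
refits search a coarser 25-point grid over the same range, which leaves
the selected models essentially unchanged while keeping 300 repeats
affordable. The final model is refit at lambda* on all data; scores are
fitted probabilities in (0, 1), classified at 0.5.

## Connectivity-map analysis

Drug profiles are per-gene treatment-vs-control differential statistics;
genes are ranked descending with ties broken by lexicographic gene id.
Enrichment of a gene set is the classic unweighted KS running sum
(+1/|hits| at members, -1/(N-|hits|) elsewhere); the enrichment score is
the extremum of larger magnitude, with exact magnitude ties resolved to
the positive extremum (documented tie-break; it arises only on
constructed inputs). The permutation null draws 1,000 random size-matched
gene sets; NES = ES / mean(|null ES| of matching sign) (normalization is
not pinned by the source method; this is the GSEA convention), and

    connectivity score CS = NES_up - NES_down

exactly, so CS > 0 means the perturbation mimics the signature. The
normalization null is keyed on (ranking, set size, seed) only, which
makes CS antisymmetry under up/down swap exact; the p-value is a
two-sided add-one permutation p of CS against null CS values formed from
independent up/down draws normalized by the same constants, with BH FDR
across profiles.

Drug similarity takes each drug's top-150 up and down genes as a
signature and scores it against every other profile; the matrix is
symmetrized as (s_ab + s_ba)/2. Consensus clustering (k = 5 by default)
average-links 1 - normalized similarity over 100 resamples of 80% of the
drugs and re-clusters the co-clustering frequency matrix. Anticorrelated
drug pairs are Spearman correlations of imputed pIC50 across patients,
kept at R <= -0.3 and BH FDR <= 0.01 — the magnitude threshold applies
regardless of significance.

## Single-sample enrichment (GSVA-style)

Per gene, expression is transformed to a cross-sample CDF estimate — a
Gaussian kernel CDF with bandwidth sd/4 for log-scale data, an empirical
CDF for counts (the kernel choice is not pinned by the source method;
both modes are exposed). Within each sample, genes are ranked by the
transformed value and weighted |N/2 - rank|^tau (tau = 1); a weighted
KS-like walk scores each set, and the score is the difference of the
walk's extrema ("max.diff", bounded in [-2, 2]). Sets need at least 5
members present (min_set configurable) and scoring needs at least 10
samples for the CDF step. Because the CDF is cross-sample and relative, a
gene set uniformly elevated in all samples carries no signal; scores
compare samples, not absolute levels.

## Statistical kernel

Wilcoxon rank-sum: exact enumeration when n_x + n_y <= 20 with no ties,
otherwise normal approximation with tie and continuity corrections; fully
tied data returns p = 1. Spearman: midranks; exact permutation p for
n <= 9 untied observations, t-approximation otherwise. BH step-up
q-values everywhere an FDR appears. Cox proportional hazards by partial
likelihood with Efron tie handling (via lifelines); CIs are
exp(estimate +/- 1.96 SE); suspected monotone-likelihood fits are flagged
with a warning, not failed. Duplicating every subject preserves the Cox
estimate only up to Efron's treatment of the ties duplication creates
(~1e-2 here). ROC AUC is the Mann-Whitney probability with midranks.
Median split assigns ties at the median to the not-above group. All tests
are two-sided with significance at p < 0.05 unless configured otherwise.

## The synthetic-data generator

All randomness flows from one seed through named sub-streams (labels,
counts, purity, scar, survival, drugs, ic50, profiles, gene sets), so
each sub-stream is independently reproducible and a fixed seed gives
bit-identical integer outputs. An optional `population_seed` lets
independent sample draws share one gene model, which is how held-out
cohorts are generated.

Defaults (one study condition, not a dial): 80 patients, 200 cell lines,
2,000 genes, 20 drugs; HR-deficient fraction 0.55; 26 up and 40 down
signature genes; 30 purity-confounded genes; shared NB dispersion 0.1;
six HRD-sensitive drugs (slope -1 of log-IC50 on the latent axis, noise
sd 0.1); scar scores Normal(57, 9) / Normal(27, 9) conditional on the
latent label, discretized and clipped at zero, which makes the >= 42 rule
~95% concordant with the truth; a quarter of deficient patients carry a
BRCA1/2 mutation and half of those carriers draw a proficient-side scar
score, exercising the mutation-only path of the call rule. Survival is
exponential with log-hazard -0.7 per latent-axis unit (deficient patients
of this treated cohort live longer), so imputed resistance to a planted
drug is a positive risk factor with closed-form truth for recovery tests.

The planted signature fold change defaults to 5. Genes planted exactly at
the selection threshold (fold change 3) would be recovered at the ~50%
sign-flip rate of an unbiased estimator, so a recovery experiment needs
planted effects above the threshold; fold change 5 sits inside the range
real HRD signature genes span (roughly 4- to 20-fold) while leaving the
3-fold configuration available explicitly.

Perturbation profiles are standard-normal noise plus
concordance * 3 z-units on the planted signature genes (sign-flipped for
the down set); concordance +1/0/-1 produces mimickers, exchangeable
nulls, and reversers.

What the generator does not emulate: L1000 landmark-to-transcriptome
inference, array platforms, per-gene dispersion heterogeneity, correlated
gene modules, cohort-specific censoring patterns, or TCGA barcode
semantics. Passing recovery tests therefore demonstrates correctness of
the estimators under the assumed models, not performance on real cohorts;
in particular the published AUCs and effect sizes are not reproduced
here, as they require the original data.

## Problem sizes used by the self-evaluation

The acceptance script and acceptance tests run: the default 80-patient /
2,000-gene cohort for signature recovery and delta-pIC50 flagging; an
independent 200-patient cohort from the same population for held-out AUC
(10 stability refits, since stability output does not enter the AUC); 150
training / 50 held-out cell lines for ridge R^2; n = 500 for Cox
recovery; 2,000 draws x 1,000 permutations for connectivity null
calibration; 1,000 genes at 100 + 100 samples for NB Wald calibration;
and 200 replicates for rank-test type-I error. A full synthetic pipeline
run (`hrd-pharmaco run-full` or the numbered analysis scripts) completes
in a few minutes on one CPU.

## Known limitations

* The DE backend inherits DESeq2's behavior; with a large fraction
  (~20%+) of truly DE genes, median-of-ratios size factors absorb part of
  the signal and attenuate fold changes — the default simulation keeps
  the DE fraction at ~3%.
* NES values for strongly planted profiles are large (the null has thin
  tails for big set shifts); they are comparable within a run, not across
  normalization schemes.
* Imputed-association inflation for truly null drugs, described above.
* The lasso stability refits resample fold assignments only (not the
  samples), matching the repeated-CV description; bootstrap stability
  selection would be a different (stricter) procedure.
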