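"""Synthetic data with the statistical structure the analysis assumes.

A latent homologous-recombination-deficiency (HRD) axis is planted into
every generated object so each downstream stage has a known truth:

* patient cohort — negative-binomial RNA counts with signature genes
  shifted in HR-deficient samples, tumor purity with purity-confounded
  genes, a genomic scar score calibrated so the >= 42 rule matches the
  latent label ~95% of the time, BRCA1/2 deleterious flags (including a
  mutation-only subgroup whose scar score stays below threshold),
  exponential survival with log-hazard linear in the latent axis, and
  per-drug binary response labels;
* cell-line panel — expression with the same planted genes driven by a
  continuous axis, log-IC50 linear in the axis for HRD-sensitive drugs
  (negative slope: deficient lines are more sensitive), plus a two-batch
  location/scale effect for batch-correction testing;
* L1000-style perturbation profiles with tunable per-drug concordance to
  the planted signature;
* paired response/resistance gene sets per drug and hallmark-style sets,
  writable as GMT.

All randomness flows from one seed through named child streams (counts,
ic50, profiles, ...) so sub-streams are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import PerturbationProfile
from .hrd_genomics import classify_hrd_status
from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    Unit,
    write_gct,
    write_gmt,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "PharmacoTrainingSet",
    "generate_cohort",
    "generate_cell_line_panel",
    "generate_perturbation_profiles",
    "generate_gene_sets",
    "write_fixture_set",
]

_STREAMS = (
    "labels", "genes", "counts", "purity", "scar", "survival",
    "drugs", "ic50", "cell_counts", "profiles", "gene_sets", "response",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(idx,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the planted-truth generator. Defaults are the study
    conditions every recovery test runs under."""

    n_patients: int = 80
    n_cell_lines: int = 200
    n_genes: int = 2000
    n_drugs: int = 20
    hrd_fraction: float = 0.55
    n_signature_up: int = 26
    n_signature_down: int = 40
    signature_log2fc: float = math.log2(5.0)
    n_purity_confounded: int = 30
    drug_effect_size: float = -1.0
    frac_hrd_sensitive_drugs: float = 0.3
    dispersion: float = 0.1
    seed: int = 0
    # secondary knobs
    ic50_noise_sd: float = 0.1
    brca_fraction: float = 0.25      # deficient patients carrying a BRCA1/2 mutation
    brca_only_fraction: float = 0.5  # of carriers: scar drawn from the proficient side
    batch_shift_log2: float = 0.8    # planted batch location shift (log2 units)
    batch_scale: float = 1.5         # planted batch dispersion multiplier
    survival_loghr: float = 0.7      # log-hazard slope on the latent axis
    profile_shift: float = 3.0       # perturbation shift (z units) at |concordance|=1
    # when set, the gene model and drug design derive from this seed instead of
    # ``seed``, so independent sample draws share one simulated population
    population_seed: int | None = None

    def __post_init__(self):
        for fld in ("n_patients", "n_cell_lines", "n_genes", "n_drugs",
                    "n_signature_up", "n_signature_down", "n_purity_confounded", "seed"):
            v = getattr(self, fld)
            if not isinstance(v, (int, np.integer)):
                raise ValueError(f"{fld} must be an integer, got {v!r}")
            if fld != "seed" and v < 0:
                raise ValueError(f"{fld} must be non-negative, got {v}")
        for fld in ("n_patients", "n_cell_lines", "n_genes", "n_drugs"):
            if getattr(self, fld) <= 0:
                raise ValueError(f"{fld} must be positive")
        if not (0.0 < self.hrd_fraction < 1.0):
            raise ValueError(f"hrd_fraction must lie strictly inside (0,1), got {self.hrd_fraction}")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be positive, got {self.dispersion}")
        if self.n_signature_up + self.n_signature_down + self.n_purity_confounded > self.n_genes:
            raise ValueError("planted gene groups exceed n_genes")
        if not (0.0 <= self.frac_hrd_sensitive_drugs <= 1.0):
            raise ValueError("frac_hrd_sensitive_drugs must lie in [0,1]")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def drug_ids(self) -> list[str]:
        return [f"DRUG{i:03d}" for i in range(1, self.n_drugs + 1)]


@dataclass
class Truth:
    up_genes: list[str]
    down_genes: list[str]
    purity_genes: list[str]
    latent_deficient: np.ndarray       # binary, per patient
    latent_axis: np.ndarray            # continuous, per patient
    drug_alpha: pd.Series              # per-drug intercept
    drug_beta: pd.Series               # per-drug slope on the axis (<0 = HRD-sensitive)
    hrd_sensitive_drugs: list[str]


@dataclass
class SyntheticCohort:
    counts: ExpressionMatrix
    purity: pd.Series
    genomic_hrd: pd.DataFrame  # sample_id, scar_score, brca flags, status
    survival_time: pd.Series
    survival_event: pd.Series
    drug_response_label: pd.DataFrame  # drugs x patients, binary (1 = sensitive)
    truth: Truth


@dataclass
class PharmacoTrainingSet:
    expression: ExpressionMatrix  # cell lines as samples, raw counts
    ic50: pd.DataFrame            # drugs x cell lines, log-scale, NaN = missing
    batch_labels: pd.Series
    truth_axis: np.ndarray | None = None

    def __post_init__(self):
        non_missing = self.ic50.notna().sum(axis=1)
        bad = non_missing[non_missing < 10]
        if len(bad):
            raise ValueError(f"drugs with <10 non-missing IC50 values: {list(bad.index)}")


# ---------------------------------------------------------------------------
# shared planted structure
# ---------------------------------------------------------------------------

def _population_seed(config: SimulationConfig) -> int:
    return config.seed if config.population_seed is None else config.population_seed


def _gene_model(config: SimulationConfig):
    """Baseline means and planted log2 effects, deterministic per seed."""
    rng = _rng(_population_seed(config), "genes")
    genes = config.gene_ids()
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=config.n_genes)
    base = np.clip(base, 5.0, None)
    up = genes[: config.n_signature_up]
    down = genes[config.n_signature_up: config.n_signature_up + config.n_signature_down]
    start = config.n_signature_up + config.n_signature_down
    purity_genes = genes[start: start + config.n_purity_confounded]
    l2fc = np.zeros(config.n_genes)
    l2fc[: config.n_signature_up] = config.signature_log2fc
    l2fc[config.n_signature_up: start] = -config.signature_log2fc
    return genes, base, l2fc, up, down, purity_genes


def _drug_design(config: SimulationConfig):
    """Per-drug intercepts and axis slopes, deterministic per seed. The
    first round(frac * n) drugs are HRD-sensitive (negative slope)."""
    rng = _rng(_population_seed(config), "drugs")
    drugs = config.drug_ids()
    n_sens = int(round(config.frac_hrd_sensitive_drugs * config.n_drugs))
    beta = np.zeros(config.n_drugs)
    beta[:n_sens] = config.drug_effect_size
    alpha = rng.normal(3.0, 1.0, size=config.n_drugs)
    return (
        pd.Series(alpha, index=drugs, name="alpha"),
        pd.Series(beta, index=drugs, name="beta"),
        drugs[:n_sens],
    )


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and Var = mu + a*mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Patient cohort with planted HRD structure (see module docstring)."""
    genes, base, l2fc, up, down, purity_genes = _gene_model(config)
    samples = [f"P{i:03d}" for i in range(1, config.n_patients + 1)]

    label_rng = _rng(config.seed, "labels")
    z = (label_rng.random(config.n_patients) < config.hrd_fraction).astype(int)
    axis = (2.0 * z - 1.0) + label_rng.normal(0.0, 0.25, config.n_patients)

    purity = pd.Series(
        _rng(config.seed, "purity").uniform(0.25, 0.95, config.n_patients),
        index=samples, name="purity",
    )

    # mean model: base * 2^(l2fc * z) for signature genes, purity scaling
    mu = base[:, None] * np.exp2(l2fc[:, None] * z[None, :])
    start = config.n_signature_up + config.n_signature_down
    pg = slice(start, start + config.n_purity_confounded)
    mu[pg, :] *= 2.0 * (1.0 - purity.to_numpy())[None, :]
    counts = _nb_draws(_rng(config.seed, "counts"), mu, config.dispersion)
    expr = ExpressionMatrix(genes, samples, counts, Unit.counts)

    # genomic scar score: label-conditional Gaussian, ~95% concordant at 42
    scar_rng = _rng(config.seed, "scar")
    scar = np.where(z == 1, scar_rng.normal(57.0, 9.0, config.n_patients),
                    scar_rng.normal(27.0, 9.0, config.n_patients))
    brca1 = np.zeros(config.n_patients, dtype=bool)
    brca2 = np.zeros(config.n_patients, dtype=bool)
    carriers = scar_rng.random(config.n_patients) < config.brca_fraction
    carriers &= z == 1
    which2 = scar_rng.random(config.n_patients) < 0.5
    brca1[carriers & ~which2] = True
    brca2[carriers & which2] = True
    # mutation-only subgroup: carriers whose scar looks proficient
    brca_only = carriers & (scar_rng.random(config.n_patients) < config.brca_only_fraction)
    scar[brca_only] = scar_rng.normal(27.0, 9.0, config.n_patients)[brca_only]
    scar = np.clip(np.round(scar), 0.0, None)

    genomic = pd.DataFrame(
        {
            "sample_id": samples,
            "scar_score": scar,
            "brca1_deleterious": brca1,
            "brca2_deleterious": brca2,
        }
    )
    genomic["status"] = [
        classify_hrd_status(s, b1, b2).value
        for s, b1, b2 in zip(scar, brca1, brca2)
    ]

    # survival: exponential, log-hazard linear in the latent axis with a
    # negative slope — HR-deficient (drug-sensitive) patients of a treated
    # cohort live longer, so imputed resistance is a positive risk factor
    surv_rng = _rng(config.seed, "survival")
    hazard = 0.1 * np.exp(-config.survival_loghr * axis)
    t_event = surv_rng.exponential(1.0 / hazard)
    censor = surv_rng.uniform(5.0, 30.0, config.n_patients)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    # per-drug binary response: median split of the planted response score
    alpha_d, beta_d, sensitive = _drug_design(config)
    resp_rng = _rng(config.seed, "response")
    labels = {}
    for drug in alpha_d.index:
        score = beta_d[drug] * axis + resp_rng.normal(0.0, 0.5, config.n_patients)
        labels[drug] = (score < np.median(score)).astype(int)  # lower score = sensitive
    label_df = pd.DataFrame(labels, index=samples).T

    truth = Truth(
        up_genes=up, down_genes=down, purity_genes=purity_genes,
        latent_deficient=z, latent_axis=axis,
        drug_alpha=alpha_d, drug_beta=beta_d, hrd_sensitive_drugs=sensitive,
    )
    return SyntheticCohort(
        counts=expr,
        purity=purity,
        genomic_hrd=genomic,
        survival_time=pd.Series(time, index=samples, name="time"),
        survival_event=pd.Series(event, index=samples, name="event"),
        drug_response_label=label_df,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# cell-line panel
# ---------------------------------------------------------------------------

def generate_cell_line_panel(config: SimulationConfig) -> PharmacoTrainingSet:
    """Cell-line expression + per-drug log-IC50 with planted linear
    dependence on a continuous latent axis; two batches with a planted
    location/scale effect."""
    if config.n_cell_lines < 10:
        raise ValueError(
            f"n_cell_lines={config.n_cell_lines} < 10: too few lines for any drug "
            "to satisfy the >=10-line usability floor"
        )
    genes, base, l2fc, *_ = _gene_model(config)
    lines = [f"CL{i:03d}" for i in range(1, config.n_cell_lines + 1)]

    rng_counts = _rng(config.seed, "cell_counts")
    axis = rng_counts.normal(0.0, 1.0, config.n_cell_lines)
    mu = base[:, None] * np.exp2(l2fc[:, None] * axis[None, :])

    # planted two-batch effect: per-gene location shift + dispersion scale in batch 2
    batch = np.array(["B1"] * (config.n_cell_lines // 2) +
                     ["B2"] * (config.n_cell_lines - config.n_cell_lines // 2))
    shift = rng_counts.normal(config.batch_shift_log2, 0.2, config.n_genes)
    in_b2 = batch == "B2"
    mu[:, in_b2] *= np.exp2(shift)[:, None]
    counts = np.empty_like(mu)
    counts[:, ~in_b2] = _nb_draws(rng_counts, mu[:, ~in_b2], config.dispersion)
    counts[:, in_b2] = _nb_draws(rng_counts, mu[:, in_b2], config.dispersion * config.batch_scale)
    expr = ExpressionMatrix(genes, lines, counts, Unit.counts)

    alpha_d, beta_d, _ = _drug_design(config)
    rng_ic50 = _rng(config.seed, "ic50")
    ic50 = (
        alpha_d.to_numpy()[:, None]
        + beta_d.to_numpy()[:, None] * axis[None, :]
        + rng_ic50.normal(0.0, config.ic50_noise_sd, (config.n_drugs, config.n_cell_lines))
    )
    # ~5% missingness, but always keep >=10 values per drug
    miss = rng_ic50.random(ic50.shape) < 0.05
    for d in range(config.n_drugs):
        if (~miss[d]).sum() < 10:
            miss[d, :] = False
    ic50 = pd.DataFrame(np.where(miss, np.nan, ic50), index=alpha_d.index, columns=lines)

    return PharmacoTrainingSet(
        expression=expr,
        ic50=ic50,
        batch_labels=pd.Series(batch, index=lines, name="batch"),
        truth_axis=axis,
    )


# ---------------------------------------------------------------------------
# perturbation profiles
# ---------------------------------------------------------------------------

def generate_perturbation_profiles(
    config: SimulationConfig,
    concordance: dict[str, float] | None = None,
    cell_line: str = "SYN-MCF7",
) -> list[PerturbationProfile]:
    """L1000-style per-gene differential statistics, one profile per drug.

    ``concordance`` maps drug id -> value in [-1, 1]: +1 up-shifts the
    planted up-signature genes and down-shifts the down genes by
    ``profile_shift`` z-units, -1 reverses the shifts, 0 is exchangeable
    noise. Drugs default to their planted role: HRD-sensitive drugs get
    concordance +1, others 0.
    """
    genes, _, l2fc, *_ = _gene_model(config)
    alpha_d, beta_d, sensitive = _drug_design(config)
    if concordance is None:
        concordance = {d: (1.0 if d in sensitive else 0.0) for d in alpha_d.index}
    bad = {d: c for d, c in concordance.items() if abs(c) > 1.0}
    if bad:
        raise ValueError(f"|concordance| > 1 for drugs: {bad}")
    rng = _rng(config.seed, "profiles")
    sig_dir = np.sign(l2fc)  # +1 for planted up genes, -1 for down, 0 otherwise
    profiles = []
    for drug in concordance:
        noise = rng.normal(0.0, 1.0, config.n_genes)
        stats = noise + concordance[drug] * config.profile_shift * sig_dir
        profiles.append(
            PerturbationProfile(
                drug_id=drug,
                cell_line=cell_line,
                stats=pd.Series(stats, index=genes),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def generate_gene_sets(
    config: SimulationConfig,
    set_size: int = 30,
    n_hallmarks: int = 10,
) -> dict[str, GeneSetCollection]:
    """Paired response/resistance sets per drug plus hallmark-style sets.

    HRD-sensitive drugs' response sets overlap the planted up-signature and
    their resistance sets overlap the down-signature, so single-sample
    enrichment recovers the planted association; null drugs get random
    disjoint sets.
    """
    genes, _, _, up, down, _ = _gene_model(config)
    alpha_d, _, sensitive = _drug_design(config)
    rng = _rng(config.seed, "gene_sets")
    background = genes[config.n_signature_up + config.n_signature_down:]

    drug_sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for drug in alpha_d.index:
        if drug in sensitive:
            k = min(set_size // 2, len(up))
            resp = list(rng.choice(up, size=k, replace=False)) + list(
                rng.choice(background, size=set_size - k, replace=False)
            )
            k2 = min(set_size // 2, len(down))
            resist = list(rng.choice(down, size=k2, replace=False)) + list(
                rng.choice(background, size=set_size - k2, replace=False)
            )
        else:
            pick = rng.choice(background, size=2 * set_size, replace=False)
            resp, resist = list(pick[:set_size]), list(pick[set_size:])
        overlap = set(resp) & set(resist)
        resist = [g for g in resist if g not in overlap] or list(
            rng.choice(background, size=set_size, replace=False)
        )
        drug_sets[f"{drug}_RESPONSE"] = sorted(set(resp))
        drug_sets[f"{drug}_RESISTANCE"] = sorted(set(resist) - set(resp))
        desc[f"{drug}_RESPONSE"] = f"synthetic response signature for {drug}"
        desc[f"{drug}_RESISTANCE"] = f"synthetic resistance signature for {drug}"

    hallmark_sets: dict[str, list[str]] = {}
    for i in range(n_hallmarks):
        size = int(rng.integers(30, 80))
        hallmark_sets[f"HALLMARK_SYN_{i + 1:02d}"] = sorted(
            rng.choice(genes, size=size, replace=False)
        )
    return {
        "drug_signatures": GeneSetCollection(sets=drug_sets, descriptions=desc),
        "hallmarks": GeneSetCollection(
            sets=hallmark_sets,
            descriptions={k: "synthetic hallmark set" for k in hallmark_sets},
        ),
    }


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

def write_fixture_set(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Generate everything and write it in the pipeline's native formats
    (GCT, GMT, TSV) plus a manifest recording config and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    panel = generate_cell_line_panel(config)
    profiles = generate_perturbation_profiles(config)
    sets = generate_gene_sets(config)

    paths = {}
    write_gct(cohort.counts, out / "patient_counts.gct")
    paths["patient_counts"] = "patient_counts.gct"
    write_gct(panel.expression, out / "cell_line_counts.gct")
    paths["cell_line_counts"] = "cell_line_counts.gct"
    panel.ic50.to_csv(out / "ic50.tsv", sep="\t")
    paths["ic50"] = "ic50.tsv"
    panel.batch_labels.to_frame().to_csv(out / "cell_line_batches.tsv", sep="\t")
    paths["cell_line_batches"] = "cell_line_batches.tsv"

    clinical = cohort.genomic_hrd.copy()
    clinical["purity"] = cohort.purity.to_numpy()
    clinical["survival_time"] = cohort.survival_time.to_numpy()
    clinical["survival_event"] = cohort.survival_event.to_numpy()
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    paths["clinical"] = "clinical.tsv"

    prof_df = pd.DataFrame({p.drug_id: p.stats for p in profiles})
    prof_expr = ExpressionMatrix(
        list(prof_df.index), list(prof_df.columns), prof_df.to_numpy(), Unit.log2
    )
    write_gct(prof_expr, out / "perturbation_profiles.gct")
    paths["perturbation_profiles"] = "perturbation_profiles.gct"

    write_gmt(sets["drug_signatures"], out / "drug_signatures.gmt")
    paths["drug_signatures"] = "drug_signatures.gmt"
    write_gmt(sets["hallmarks"], out / "hallmarks.gmt")
    paths["hallmarks"] = "hallmarks.gmt"

    manifest = {"config": dataclasses.asdict(config), "files": paths}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = "manifest.json"
    return paths
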