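"""End-to-end orchestration of the HRD pharmacogenomic analysis.

Stage order mirrors the analysis: genomic HRD call -> pIC50 imputation and
per-drug delta-pIC50 -> HRD transcriptomic signature and score ->
connectivity-map scoring and drug clustering -> single-sample enrichment
(DRscore / hallmarks) -> survival regression. Every stage emits a plain
TSV so any stage can be re-entered, and a run record captures the resolved
config, seed, stage timings and output digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import connectivity as conn
from . import drug_response as dr
from . import enrichment as enr
from . import signature as sig
from . import synthetic as syn
from .io_formats import ExpressionMatrix, Unit
from .stats import cox_fit

logger = logging.getLogger(__name__)

__all__ = ["PipelineRunRecord", "StageError", "validate_config", "resolve_config", "run_full"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulation": {f.name: f.default for f in dataclasses.fields(syn.SimulationConfig)
                   if f.name != "seed"},
    "drug_response": {"max_zero_samples": 5, "pseudocount": 1.0, "center": "mean"},
    "signature": {"fdr_max": 0.01, "fc_min": 3.0, "purity_p_max": 0.05,
                  "n_folds": 10, "n_refits": 300, "n_lambda": 100, "holdout_fraction": 0.25},
    "connectivity": {"n_perm": 1000, "top_n": 150, "k_clusters": 5,
                     "n_resamples": 100, "subsample": 0.8,
                     "r_max": -0.3, "fdr_max": 0.01},
    "enrichment": {"tau": 1.0, "min_set": 5},
    "hrd": {"scar_threshold": 42.0},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineRunRecord:
    config: dict
    seed: int
    stage_timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # file -> sha256 digest
    warnings: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _merge(base: dict, override: dict, path="") -> tuple[dict, list[str]]:
    out = dict(base)
    errors = []
    for key, val in override.items():
        if key not in base:
            errors.append(f"unknown config key {path + key!r}")
            continue
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key], sub = _merge(base[key], val, path=f"{path}{key}.")
            errors.extend(sub)
        else:
            out[key] = val
    return out, errors


def validate_config(source) -> tuple[dict, list[str]]:
    """Resolve a config (path to YAML, dict, or None) against the schema.

    Returns (resolved config, error list). Unknown keys and invalid values
    are errors naming the key; a missing seed is defaulted with a warning.
    """
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    if "seed" not in user:
        warnings.warn("config has no seed; defaulting to 0", stacklevel=2)
    cfg, errors = _merge(DEFAULT_CONFIG, user)
    sim = cfg["simulation"]
    try:
        syn.SimulationConfig(seed=int(cfg["seed"]), **sim)
    except (ValueError, TypeError) as exc:
        errors.append(str(exc))
    return cfg, errors


def resolve_config(source) -> dict:
    cfg, errors = validate_config(source)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, record: PipelineRunRecord, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    record.outputs[path.name] = _digest(path)


def run_full(config=None, out_dir="pipeline_out", skip=()) -> PipelineRunRecord:
    """Run the full synthetic analysis; one TSV per result table.

    ``skip`` names stages to omit ("connectivity", "enrichment",
    "survival"); skipped stages are marked in the run record. Any stage
    error aborts with the stage name; partial outputs persist.
    """
    cfg = resolve_config(config)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = PipelineRunRecord(config=cfg, seed=seed, skipped=list(skip))
    logger.info("run_full: seed=%d out_dir=%s", seed, out)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                record.stage_timings[name] = round(time.perf_counter() - self.t0, 3)
                with open(out / "run_record.json", "w") as fh:
                    fh.write(record.to_json())
                if exc is not None:
                    raise StageError(name, exc) from exc
        return _Ctx()

    with stage("synthesize"):
        sim = syn.SimulationConfig(seed=seed, **cfg["simulation"])
        cohort = syn.generate_cohort(sim)
        panel = syn.generate_cell_line_panel(sim)
        profiles = syn.generate_perturbation_profiles(sim)
        gene_sets = syn.generate_gene_sets(sim)

    with stage("hrd_call"):
        genomic = cohort.genomic_hrd
        status = pd.Series(genomic["status"].to_numpy(), index=genomic["sample_id"])
        _write(genomic, out / "hrd_status.tsv", record, index=False)

    with stage("impute_pic50"):
        imputation = dr.fit_ridge_models(
            panel, cohort.counts, seed=seed,
            max_zero_samples=cfg["drug_response"]["max_zero_samples"],
            pseudocount=cfg["drug_response"]["pseudocount"],
        )
        pic50 = dr.predict_pic50(imputation)
        delta = dr.delta_pic50_table(pic50, status, center=cfg["drug_response"]["center"])
        _write(pic50, out / "pic50.tsv", record)
        _write(delta, out / "delta_pic50.tsv", record)

    with stage("signature"):
        de = sig.nb_wald_test(cohort.counts, status.reindex(cohort.counts.sample_ids))
        up, down = sig.select_signature(
            de, fdr_max=cfg["signature"]["fdr_max"], fc_min=cfg["signature"]["fc_min"]
        )
        log2_expr = dr.log2_transform(cohort.counts)
        hrd_sig = sig.purity_filter(
            (up, down), log2_expr, cohort.purity, p_max=cfg["signature"]["purity_p_max"]
        )
        _write(de, out / "differential_expression.tsv", record)
        sig_df = pd.DataFrame(
            {"gene_id": hrd_sig.genes,
             "direction": ["up"] * len(hrd_sig.up_genes) + ["down"] * len(hrd_sig.down_genes)}
        )
        _write(sig_df, out / "hrd_signature.tsv", record, index=False)

        model_genes = hrd_sig.genes if hrd_sig.genes else (up + down)
        model = sig.fit_hrd_score(
            log2_expr, status.reindex(log2_expr.sample_ids), genes=model_genes,
            n_folds=cfg["signature"]["n_folds"], n_refits=cfg["signature"]["n_refits"],
            n_lambda=cfg["signature"]["n_lambda"], seed=seed,
        )
        scores = sig.predict_hrd_score(model, log2_expr)
        auc = sig.roc_auc(scores.to_numpy(), (status.reindex(scores.index) == "HR_deficient"))
        model_df = pd.DataFrame({"gene": model.genes, "weight": model.weights})
        model_df.loc[len(model_df)] = ["(intercept)", model.intercept]
        model_df.loc[len(model_df)] = ["(lambda)", model.lambda_]
        _write(model_df, out / "hrd_score_model.tsv", record, index=False)
        _write(scores.to_frame(), out / "hrd_scores.tsv", record)
        record.warnings.append(f"training AUC vs genomic status: {auc:.3f}")

    if "connectivity" not in skip:
        with stage("connectivity"):
            cmap = conn.score_profiles(
                profiles, hrd_sig.up_genes or up, hrd_sig.down_genes or down,
                n_perm=cfg["connectivity"]["n_perm"], seed=seed,
            )
            _write(cmap, out / "connectivity.tsv", record, index=False)
            simmat = conn.similarity_matrix(
                profiles, top_n=cfg["connectivity"]["top_n"], seed=seed
            )
            labels, consensus = conn.consensus_cluster(
                simmat, k=cfg["connectivity"]["k_clusters"],
                n_resamples=cfg["connectivity"]["n_resamples"],
                subsample=cfg["connectivity"]["subsample"], seed=seed,
            )
            _write(labels.to_frame(), out / "drug_clusters.tsv", record)
            _write(consensus, out / "consensus_matrix.tsv", record)
            pairs = conn.anticorrelated_pairs(
                pic50, r_max=cfg["connectivity"]["r_max"],
                fdr_max=cfg["connectivity"]["fdr_max"],
            )
            _write(pairs, out / "anticorrelated_pairs.tsv", record, index=False)

    if "enrichment" not in skip:
        with stage("enrichment"):
            log2_expr = dr.log2_transform(cohort.counts)
            drs = enr.gsva_scores(
                log2_expr, gene_sets["drug_signatures"],
                tau=cfg["enrichment"]["tau"], min_set=cfg["enrichment"]["min_set"],
            )
            hms = enr.gsva_scores(
                log2_expr, gene_sets["hallmarks"],
                tau=cfg["enrichment"]["tau"], min_set=cfg["enrichment"]["min_set"],
            )
            dr_tests = enr.drscore_hrd_table(drs, status)
            corr = enr.drug_hallmark_correlations(drs.scores, hms.scores)
            edges = enr.build_drug_target_pathway_table(corr)
            _write(drs.scores, out / "drscores.tsv", record)
            _write(hms.scores, out / "hallmark_scores.tsv", record)
            _write(dr_tests, out / "drscore_hrd_tests.tsv", record)
            _write(corr, out / "drug_hallmark_correlations.tsv", record, index=False)
            _write(edges, out / "network_edges.tsv", record, index=False)

    if "survival" not in skip:
        with stage("survival"):
            rows = []
            for drug in pic50.index:
                x = pic50.loc[drug].reindex(cohort.survival_time.index)
                try:
                    fit = cox_fit(
                        cohort.survival_time.to_numpy(),
                        cohort.survival_event.to_numpy(),
                        x.to_numpy(), names=[drug],
                    )
                except ValueError as exc:
                    record.warnings.append(f"survival: {drug}: {exc}")
                    continue
                s = fit.summary().iloc[0]
                rows.append((drug, s.log_hr, s.se, s.hr, s.ci_lower, s.ci_upper, s.p_value,
                             fit.n, fit.n_events))
            surv = pd.DataFrame(
                rows, columns=["drug_id", "log_hr", "se", "hr", "ci_lower", "ci_upper",
                               "p_value", "n", "n_events"],
            )
            _write(surv, out / "survival_cox.tsv", record, index=False)

    with open(out / "run_record.json", "w") as fh:
        fh.write(record.to_json())
    return record
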