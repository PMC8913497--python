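"""Genomic homologous-recombination-deficiency (HRD) calling.

A sample is HR-deficient when its genomic scar score (LOH + LST + ntAI
index) reaches a threshold (default 42, inclusive) or when it carries a
deleterious BRCA1/2 mutation; otherwise it is HR-proficient. The
deleteriousness rule for mutations is pluggable; the default counts
truncating variants (nonsense, frameshift, splice-site) and entries
pre-annotated as deleterious.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .io_formats import MutationTable

logger = logging.getLogger(__name__)

__all__ = [
    "HRDStatus",
    "GenomicHRDRecord",
    "classify_hrd_status",
    "flag_deleterious",
    "DEFAULT_SCAR_THRESHOLD",
    "TRUNCATING_CLASSES",
]

DEFAULT_SCAR_THRESHOLD = 42.0

# Variant classes counted as deleterious by the default truncating-variant rule
# (case-insensitive match on the variant_classification string).
TRUNCATING_CLASSES = frozenset(
    {
        "nonsense_mutation",
        "nonsense",
        "frame_shift_del",
        "frame_shift_ins",
        "frameshift",
        "frameshift_deletion",
        "frameshift_insertion",
        "splice_site",
        "splice_site_mutation",
    }
)

NEUTRAL_CLASSES = frozenset(
    {
        "silent",
        "synonymous",
        "intron",
        "intronic",
        "3'utr",
        "5'utr",
        "missense_mutation",
        "missense",
        "in_frame_del",
        "in_frame_ins",
    }
)


class HRDStatus(str, Enum):
    deficient = "HR_deficient"
    proficient = "HR_proficient"
    missing = "missing"


@dataclass(frozen=True)
class GenomicHRDRecord:
    sample_id: str
    scar_score: float  # NaN when missing
    brca1_deleterious: bool | None
    brca2_deleterious: bool | None
    status: HRDStatus

    @staticmethod
    def build(sample_id, scar_score, brca1, brca2, threshold=DEFAULT_SCAR_THRESHOLD):
        status = classify_hrd_status(scar_score, brca1, brca2, threshold=threshold)
        return GenomicHRDRecord(str(sample_id), float("nan") if scar_score is None else float(scar_score), brca1, brca2, status)


def classify_hrd_status(
    scar_score,
    brca1_deleterious,
    brca2_deleterious,
    threshold: float = DEFAULT_SCAR_THRESHOLD,
) -> HRDStatus:
    """HR_deficient iff scar_score >= threshold (inclusive) OR either BRCA
    flag is deleterious.

    Missing scar score with no mutation flag set propagates as a missing
    status rather than being imputed. A negative scar score is an error.
    """
    scar_missing = scar_score is None or (isinstance(scar_score, float) and np.isnan(scar_score))
    if not scar_missing:
        scar_score = float(scar_score)
        if scar_score < 0:
            raise ValueError(f"negative scar score: {scar_score}")
    if brca1_deleterious or brca2_deleterious:
        return HRDStatus.deficient
    if scar_missing:
        return HRDStatus.missing
    if scar_score >= threshold:
        return HRDStatus.deficient
    return HRDStatus.proficient


def _is_deleterious(classification, preannotated) -> bool:
    if preannotated is not None and not (isinstance(preannotated, float) and np.isnan(preannotated)):
        return bool(preannotated)
    cls = str(classification).strip().lower()
    if cls in TRUNCATING_CLASSES:
        return True
    if cls not in NEUTRAL_CLASSES:
        logger.warning("unknown variant classification %r counted as non-deleterious", classification)
    return False


def flag_deleterious(
    mutations: MutationTable,
    genes=("BRCA1", "BRCA2"),
    rule=_is_deleterious,
) -> pd.DataFrame:
    """Per-sample deleterious-mutation flags for the given genes.

    Returns a DataFrame indexed by sample_id with one boolean column per
    gene (``brca1_deleterious`` style names). Samples appear iff they have
    at least one mutation row; absent samples carry no information.
    """
    df = mutations.records
    samples = sorted(df["sample_id"].unique())
    flags = pd.DataFrame(
        False, index=pd.Index(samples, name="sample_id"),
        columns=[f"{g.lower()}_deleterious" for g in genes],
    )
    for _, row in df.iterrows():
        gene = row["gene"]
        if gene not in genes:
            continue
        if rule(row["variant_classification"], row["deleterious"]):
            flags.loc[row["sample_id"], f"{gene.lower()}_deleterious"] = True
    return flags


def call_cohort(
    clinical: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    threshold: float = DEFAULT_SCAR_THRESHOLD,
) -> pd.DataFrame:
    """Apply the HRD rule across a clinical table with a ``scar_score``
    column, joining per-sample mutation flags when given."""
    if "sample_id" not in clinical.columns or "scar_score" not in clinical.columns:
        raise ValueError("clinical table needs sample_id and scar_score columns")
    out = clinical[["sample_id", "scar_score"]].copy()
    for col in ("brca1_deleterious", "brca2_deleterious"):
        if col in clinical.columns:
            out[col] = clinical[col].astype("boolean")
        else:
            out[col] = pd.NA
    if flags is not None:
        joined = out.set_index("sample_id").join(flags, rsuffix="_mut")
        for col in ("brca1_deleterious", "brca2_deleterious"):
            mut_col = f"{col}_mut"
            if mut_col in joined.columns:
                joined[col] = joined[col].fillna(False) | joined[mut_col].fillna(False)
        out = joined.reset_index()[["sample_id", "scar_score", "brca1_deleterious", "brca2_deleterious"]]
    out["status"] = [
        classify_hrd_status(
            None if pd.isna(r.scar_score) else float(r.scar_score),
            bool(r.brca1_deleterious) if not pd.isna(r.brca1_deleterious) else None,
            bool(r.brca2_deleterious) if not pd.isna(r.brca2_deleterious) else None,
            threshold=threshold,
        ).value
        for r in out.itertuples()
    ]
    return out
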