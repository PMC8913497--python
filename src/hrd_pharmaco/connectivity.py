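"""Connectivity-map scoring of up/down gene signatures against
drug-perturbed ranked expression profiles.

The enrichment statistic is the classic (unweighted) Kolmogorov-Smirnov
running sum over a ranked gene list: the walk rises by 1/|hits| at member
genes and falls by 1/(N - |hits|) elsewhere; the enrichment score (ES) is
the extremum of larger magnitude (positive maxima win ties). ES values are
normalized against a permutation null of size-matched random gene sets:
NES = ES / mean(|null ES| of matching sign), and the connectivity score of
a signature against a drug profile is

    CS = NES_up - NES_down

so CS > 0 means the perturbation mimics the signature (up-set pushed up,
down-set pushed down) and CS < 0 means it reverses it. Two-sided
permutation p-values use the add-one convention p = (1 + #{|null| >=
|obs|}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationProfile",
    "DrugSignature",
    "ConnectivityResult",
    "ks_enrichment",
    "permute_nes",
    "normalize_es",
    "permutation_p",
    "connectivity_score",
    "score_signature",
    "score_profiles",
    "extract_drug_signature",
    "drug_similarity",
    "similarity_matrix",
    "consensus_cluster",
    "anticorrelated_pairs",
]


@dataclass
class PerturbationProfile:
    """Treatment-vs-control differential expression of one drug in one cell
    line; larger statistic = more up-regulated under treatment."""

    drug_id: str
    cell_line: str
    stats: pd.Series  # index: gene ids
    dose: float = 10.0
    dose_unit: str = "uM"
    time: float = 24.0
    time_unit: str = "h"
    _ranking: list[str] | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.stats.index.duplicated().any():
            raise ValueError("duplicate gene ids in perturbation profile")

    @property
    def ranking(self) -> list[str]:
        """Genes in descending order of the differential statistic; ties
        broken by lexicographic gene id (deterministic)."""
        if self._ranking is None:
            order = sorted(self.stats.index, key=lambda g: (-self.stats[g], g))
            self._ranking = order
        return self._ranking


@dataclass(frozen=True)
class DrugSignature:
    drug_id: str
    top_up: list[str]
    top_down: list[str]

    def __post_init__(self):
        if set(self.top_up) & set(self.top_down):
            raise ValueError("up and down signature sets overlap")


@dataclass(frozen=True)
class ConnectivityResult:
    drug_id: str
    cell_line: str
    es_up: float
    es_down: float
    nes_up: float
    nes_down: float
    connectivity_score: float
    p_value: float
    fdr: float = float("nan")


class UnscorableError(ValueError):
    """Gene set has no members in the ranked profile."""


def _es_from_positions(positions: np.ndarray, n_genes: int, n_hits: int) -> float:
    """ES given sorted 0-based hit positions within a ranking of n_genes."""
    i = np.arange(n_hits)
    # walk value just after the i-th hit, and just before it
    after = (i + 1) / n_hits - (positions - i) / (n_genes - n_hits)
    before = i / n_hits - (positions - i) / (n_genes - n_hits)
    pos_max = max(0.0, float(after.max()))
    neg_min = min(0.0, float(before.min()))
    # positive extremum wins magnitude ties (documented tie-break)
    return pos_max if pos_max >= -neg_min else neg_min


def ks_enrichment(ranking, gene_set) -> float:
    """Classic KS running-sum enrichment score of ``gene_set`` within the
    ordered gene list ``ranking``; ES in [-1, 1]."""
    ranking = list(ranking)
    n = len(ranking)
    members = set(gene_set)
    if len(members) >= n:
        raise ValueError("gene set must be smaller than the ranked universe")
    positions = np.array([i for i, g in enumerate(ranking) if g in members], dtype=float)
    if positions.size == 0:
        raise UnscorableError("gene set has empty intersection with the ranking")
    return _es_from_positions(positions, n, positions.size)


def _null_es_sample(n_genes: int, set_size: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null ES values for random gene sets of the given size (vectorized)."""
    # random size-k subsets of 0..N-1 via argpartition of uniform keys
    keys = rng.random((n_perm, n_genes))
    pos = np.sort(np.argpartition(keys, set_size - 1, axis=1)[:, :set_size], axis=1).astype(float)
    i_idx = np.arange(set_size)[None, :]
    after = (i_idx + 1) / set_size - (pos - i_idx) / (n_genes - set_size)
    before = i_idx / set_size - (pos - i_idx) / (n_genes - set_size)
    pos_max = np.maximum(after.max(axis=1), 0.0)
    neg_min = np.minimum(before.min(axis=1), 0.0)
    return np.where(pos_max >= -neg_min, pos_max, neg_min)


def permute_nes(ranking, set_size: int, n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """Sample the permutation null of the KS enrichment score by drawing
    random gene sets of ``set_size`` from the ranking's universe."""
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    n = len(ranking)
    rng = np.random.default_rng(seed)
    return _null_es_sample(n, set_size, n_perm, rng)


def normalize_es(es: float, null_es: np.ndarray) -> float:
    """NES = ES / mean(|null ES| of matching sign); NES sign equals ES sign."""
    if es == 0.0:
        return 0.0
    same_sign = null_es[null_es > 0] if es > 0 else null_es[null_es < 0]
    if same_sign.size < 10:
        warnings.warn("fewer than 10 same-sign null ES values; NES unstable", stacklevel=2)
        if same_sign.size == 0:
            return float(np.sign(es)) * abs(es) / (np.abs(null_es).mean() or 1.0)
    return float(es / np.abs(same_sign).mean())


def permutation_p(obs: float, null: np.ndarray) -> float:
    """Two-sided add-one permutation p-value on |obs| against |null|."""
    n_perm = null.size
    return float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1))


def connectivity_score(nes_up: float, nes_down: float) -> float:
    """CS = NES_up - NES_down, exactly."""
    if not (np.isfinite(nes_up) and np.isfinite(nes_down)):
        raise ValueError("NES values must be finite")
    return nes_up - nes_down


def score_signature(
    profile: PerturbationProfile,
    up_genes,
    down_genes,
    n_perm: int = 1000,
    seed: int = 0,
) -> ConnectivityResult:
    """Connectivity of an up/down signature against one drug profile.

    The p-value is a two-sided permutation p of the connectivity score
    against paired null CS values built from the same random-set nulls used
    for normalization.
    """
    ranking = profile.ranking
    up_present = [g for g in up_genes if g in profile.stats.index]
    down_present = [g for g in down_genes if g in profile.stats.index]
    if not up_present or not down_present:
        raise UnscorableError(
            f"signature has empty intersection with profile {profile.drug_id}/{profile.cell_line}"
        )
    n = len(ranking)
    es_up = ks_enrichment(ranking, up_present)
    es_down = ks_enrichment(ranking, down_present)
    # normalization null depends only on (ranking size, set size, seed), so
    # swapping the up and down sets negates the connectivity score exactly
    k_up, k_down = len(up_present), len(down_present)
    null_norm_up = _null_es_sample(n, k_up, n_perm, np.random.default_rng((seed, k_up)))
    null_norm_down = (
        null_norm_up if k_down == k_up
        else _null_es_sample(n, k_down, n_perm, np.random.default_rng((seed, k_down)))
    )
    nes_up = normalize_es(es_up, null_norm_up)
    nes_down = normalize_es(es_down, null_norm_down)
    cs = connectivity_score(nes_up, nes_down)
    # null CS from independent up/down draws, normalized by the same constants
    null_a = _null_es_sample(n, k_up, n_perm, np.random.default_rng((seed, 1, k_up)))
    null_b = _null_es_sample(n, k_down, n_perm, np.random.default_rng((seed, 2, k_down)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_cs = np.array(
            [normalize_es(u, null_norm_up) - normalize_es(d, null_norm_down)
             for u, d in zip(null_a, null_b)]
        )
    p = permutation_p(cs, null_cs)
    return ConnectivityResult(
        drug_id=profile.drug_id,
        cell_line=profile.cell_line,
        es_up=es_up,
        es_down=es_down,
        nes_up=nes_up,
        nes_down=nes_down,
        connectivity_score=cs,
        p_value=p,
    )


def score_profiles(profiles, up_genes, down_genes, n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Score a signature against many profiles; BH FDR across profiles.
    Unscorable profiles are dropped with a logged warning."""
    rows = []
    for i, prof in enumerate(profiles):
        try:
            res = score_signature(prof, up_genes, down_genes, n_perm=n_perm, seed=seed + i)
        except UnscorableError as exc:
            logger.warning("skipping profile: %s", exc)
            continue
        rows.append(res)
    df = pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in rows],
            "cell_line": [r.cell_line for r in rows],
            "es_up": [r.es_up for r in rows],
            "es_down": [r.es_down for r in rows],
            "nes_up": [r.nes_up for r in rows],
            "nes_down": [r.nes_down for r in rows],
            "connectivity_score": [r.connectivity_score for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
    df["fdr"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    return df


def extract_drug_signature(profile: PerturbationProfile, top_n: int = 150) -> DrugSignature:
    """Top-n most up- and down-regulated genes of a profile; ties broken by
    lexicographic gene id."""
    if profile.stats.size < 2 * top_n:
        raise ValueError(
            f"profile has {profile.stats.size} genes; need at least {2 * top_n}"
        )
    up_order = sorted(profile.stats.index, key=lambda g: (-profile.stats[g], g))
    down_order = sorted(profile.stats.index, key=lambda g: (profile.stats[g], g))
    return DrugSignature(
        drug_id=profile.drug_id,
        top_up=up_order[:top_n],
        top_down=down_order[:top_n],
    )


def drug_similarity(
    sig: DrugSignature,
    profile: PerturbationProfile,
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """Similarity of drug a to drug b: connectivity score of a's top-up/down
    signature against b's ranked profile."""
    shared_up = [g for g in sig.top_up if g in profile.stats.index]
    shared_down = [g for g in sig.top_down if g in profile.stats.index]
    if not shared_up and not shared_down:
        raise ValueError("disjoint gene universes between signature and profile")
    res = score_signature(profile, shared_up, shared_down, n_perm=n_perm, seed=seed)
    return res.connectivity_score


def similarity_matrix(
    profiles,
    top_n: int = 150,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Symmetrized drug x drug connectivity-similarity matrix:
    S = (s_ab + s_ba) / 2 with s_ab = CS(signature(a), profile(b)).

    The permutation null depends only on (profile, set size), so one null
    per profile is shared across all query signatures.
    """
    sigs = [extract_drug_signature(p, top_n=top_n) for p in profiles]
    drugs = [p.drug_id for p in profiles]
    n = len(profiles)
    raw = np.zeros((n, n))
    for b, prof in enumerate(profiles):
        ranking = prof.ranking
        rng = np.random.default_rng(seed + b)
        k_up = len([g for g in sigs[0].top_up if g in prof.stats.index])
        null = _null_es_sample(len(ranking), max(k_up, 1), n_perm, rng)
        for a, sig in enumerate(sigs):
            up = [g for g in sig.top_up if g in prof.stats.index]
            down = [g for g in sig.top_down if g in prof.stats.index]
            if not up or not down:
                raise ValueError("disjoint gene universes in similarity matrix")
            es_u = ks_enrichment(ranking, up)
            es_d = ks_enrichment(ranking, down)
            raw[a, b] = connectivity_score(normalize_es(es_u, null), normalize_es(es_d, null))
    sym = (raw + raw.T) / 2.0
    return pd.DataFrame(sym, index=drugs, columns=drugs)


def consensus_cluster(
    similarity: pd.DataFrame,
    k: int = 5,
    n_resamples: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Consensus clustering of drugs from a similarity matrix.

    Each resample draws ``subsample`` of the drugs, average-linkage
    clusters them on distance 1 - normalized similarity, and records
    co-clustering; the consensus matrix (co-cluster frequency among
    co-sampled pairs) is itself clustered for the final labels.
    """
    n = similarity.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of drugs ({n})")
    S = similarity.to_numpy().astype(float)
    smin, smax = S.min(), S.max()
    norm = (S - smin) / (smax - smin) if smax > smin else np.ones_like(S)
    np.fill_diagonal(norm, 1.0)
    dist = 1.0 - norm
    rng = np.random.default_rng(seed)
    m = max(k, int(np.ceil(subsample * n)))
    co = np.zeros((n, n))
    tog = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = dist[np.ix_(idx, idx)]
        sub = (sub + sub.T) / 2.0
        np.fill_diagonal(sub, 0.0)
        labels = fcluster(average(squareform(sub, checks=False)), t=k, criterion="maxclust")
        tog[np.ix_(idx, idx)] += 1
        same = labels[:, None] == labels[None, :]
        co[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(tog > 0, co / np.maximum(tog, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0
    final_dist = 1.0 - consensus
    np.fill_diagonal(final_dist, 0.0)
    final = fcluster(average(squareform(final_dist, checks=False)), t=k, criterion="maxclust")
    labels = pd.Series(final, index=similarity.index, name="cluster")
    cons_df = pd.DataFrame(consensus, index=similarity.index, columns=similarity.columns)
    return labels, cons_df


def anticorrelated_pairs(
    pic50: pd.DataFrame,
    r_max: float = -0.3,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Significantly negatively correlated drug pairs by imputed response:
    Spearman across patients, BH FDR over all pairs, keep R <= r_max and
    FDR <= fdr_max."""
    if pic50.shape[1] < 10:
        raise ValueError("need at least 10 patients")
    drugs = list(pic50.index)
    rho, p = sps.spearmanr(pic50.to_numpy().T)
    if np.isscalar(rho) or np.ndim(rho) == 0:  # scalar for exactly two drugs
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    rows = []
    iu = np.triu_indices(len(drugs), k=1)
    pvals = p[iu]
    qvals = bh_fdr(pvals)
    for (i, j), pv, qv in zip(zip(*iu), pvals, qvals):
        rows.append((drugs[i], drugs[j], rho[i, j], pv, qv))
    table = pd.DataFrame(rows, columns=["drug_a", "drug_b", "rho", "p_value", "fdr"])
    kept = table[(table["rho"] <= r_max) & (table["fdr"] <= fdr_max)].reset_index(drop=True)
    return kept
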