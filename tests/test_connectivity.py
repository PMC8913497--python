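"""Connectivity-map scoring: KS enrichment, permutation NES, drug
signatures, similarity, consensus clustering, anticorrelated pairs."""

import numpy as np
import pandas as pd
import pytest

from hrd_pharmaco.connectivity import (
    DrugSignature,
    PerturbationProfile,
    UnscorableError,
    anticorrelated_pairs,
    connectivity_score,
    consensus_cluster,
    extract_drug_signature,
    ks_enrichment,
    normalize_es,
    permutation_p,
    permute_nes,
    score_signature,
    similarity_matrix,
)


def brute_force_walk(ranking, members):
    """Independent oracle: step the running sum and return its extrema."""
    members = set(members)
    k = sum(1 for g in ranking if g in members)
    n = len(ranking)
    value, values = 0.0, [0.0]
    for g in ranking:
        value += 1.0 / k if g in members else -1.0 / (n - k)
        values.append(value)
    return max(values), min(values)


def _profile(stats: dict, drug="D", cell="C"):
    return PerturbationProfile(drug_id=drug, cell_line=cell, stats=pd.Series(stats))


class TestKSEnrichment:
    def test_top_block_gives_plus_one(self):
        ranking = [f"g{i}" for i in range(10)]
        assert ks_enrichment(ranking, ranking[:3]) == pytest.approx(1.0)

    def test_bottom_block_gives_minus_one(self):
        ranking = [f"g{i}" for i in range(10)]
        assert ks_enrichment(ranking, ranking[-3:]) == pytest.approx(-1.0)

    def test_five_gene_walk_matches_enumeration(self):
        ranking = ["g1", "g2", "g3", "g4", "g5"]
        hits = ["g2", "g4"]
        hi, lo = brute_force_walk(ranking, hits)
        assert hi == pytest.approx(1 / 3) and lo == pytest.approx(-1 / 3)
        # magnitude tie resolves to the positive extremum
        assert ks_enrichment(ranking, hits) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_oracle_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        ranking = [f"g{i}" for i in range(n)]
        k = int(rng.integers(1, n - 1))
        members = list(rng.choice(ranking, size=k, replace=False))
        hi, lo = brute_force_walk(ranking, members)
        expected = hi if hi >= -lo else lo
        es = ks_enrichment(ranking, members)
        assert es == pytest.approx(expected, abs=1e-12)
        assert -1.0 <= es <= 1.0

    def test_walk_conservation_returns_to_zero(self):
        rng = np.random.default_rng(4)
        ranking = [f"g{i}" for i in range(40)]
        members = list(rng.choice(ranking, size=11, replace=False))
        k, n = len(members), len(ranking)
        end = k * (1 / k) + (n - k) * (-1 / (n - k))
        assert end == pytest.approx(0.0)

    def test_empty_intersection_unscorable(self):
        with pytest.raises(UnscorableError):
            ks_enrichment(["a", "b", "c"], ["z"])


class TestPermutationNull:
    def test_zero_es_gives_zero_nes_and_p_near_one(self):
        null = permute_nes([f"g{i}" for i in range(100)], set_size=10, n_perm=200, seed=0)
        assert normalize_es(0.0, null) == 0.0
        assert permutation_p(0.0, null) == pytest.approx(1.0)

    def test_nes_sign_matches_es_sign(self):
        null = permute_nes([f"g{i}" for i in range(100)], set_size=10, n_perm=200, seed=0)
        assert normalize_es(0.5, null) > 0
        assert normalize_es(-0.5, null) < 0

    def test_doubling_permutations_stable(self):
        ranking = [f"g{i}" for i in range(200)]
        n1 = permute_nes(ranking, 20, n_perm=1000, seed=1)
        n2 = permute_nes(ranking, 20, n_perm=2000, seed=2)
        nes1, nes2 = normalize_es(0.6, n1), normalize_es(0.6, n2)
        assert nes1 == pytest.approx(nes2, rel=0.1)

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValueError):
            permute_nes(["a", "b", "c", "d"], 2, n_perm=50)


class TestConnectivityScore:
    def test_exact_subtraction(self):
        assert connectivity_score(1.0, -1.0) == 2.0

    def test_antisymmetric_under_up_down_swap(self):
        rng = np.random.default_rng(7)
        stats = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=80))}
        prof = _profile(stats)
        up = [f"g{i}" for i in range(0, 10)]
        down = [f"g{i}" for i in range(40, 50)]
        a = score_signature(prof, up, down, n_perm=300, seed=5)
        b = score_signature(prof, down, up, n_perm=300, seed=5)
        assert a.connectivity_score == pytest.approx(-b.connectivity_score, abs=1e-9)

    def test_cs_equals_nes_difference_exactly(self):
        rng = np.random.default_rng(8)
        stats = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=60))}
        res = score_signature(_profile(stats), ["g0", "g1", "g2"], ["g10", "g11"],
                              n_perm=200, seed=0)
        assert res.connectivity_score == res.nes_up - res.nes_down

    def test_nonfinite_nes_rejected(self):
        with pytest.raises(ValueError):
            connectivity_score(np.nan, 0.0)


class TestDrugSignature:
    def test_monotone_profile_gives_exact_blocks(self):
        stats = {f"g{i:02d}": float(100 - i) for i in range(20)}
        sig = extract_drug_signature(_profile(stats), top_n=5)
        assert sig.top_up == [f"g{i:02d}" for i in range(5)]
        assert sig.top_down == [f"g{i:02d}" for i in range(19, 14, -1)]

    def test_tied_boundary_resolved_lexicographically(self):
        stats = {"gA": 3.0, "gB": 2.0, "gC": 2.0, "gD": 1.0, "gE": 0.0, "gF": -1.0}
        sig = extract_drug_signature(_profile(stats), top_n=2)
        assert sig.top_up == ["gA", "gB"]  # gB beats gC on the tie

    def test_signature_genes_exist_in_profile(self):
        rng = np.random.default_rng(1)
        stats = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=30))}
        sig = extract_drug_signature(_profile(stats), top_n=5)
        assert set(sig.top_up) <= set(stats) and set(sig.top_down) <= set(stats)

    def test_too_small_profile_rejected(self):
        with pytest.raises(ValueError):
            extract_drug_signature(_profile({"a": 1.0, "b": 0.0}), top_n=2)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            DrugSignature("d", ["a", "b"], ["b", "c"])


def _mechanism_profiles(n_genes=200, n_per_group=3, seed=0):
    """Two planted mechanism groups with opposite perturbation patterns."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    signature = np.zeros(n_genes)
    signature[:40] = 4.0
    signature[40:80] = -4.0
    profiles = []
    for i in range(n_per_group):
        profiles.append(_profile(dict(zip(genes, signature + rng.normal(size=n_genes))),
                                 drug=f"A{i}"))
    for i in range(n_per_group):
        profiles.append(_profile(dict(zip(genes, -signature + rng.normal(size=n_genes))),
                                 drug=f"B{i}"))
    return profiles


class TestSimilarityAndClustering:
    def test_similarity_structure(self):
        profiles = _mechanism_profiles()
        sim = similarity_matrix(profiles, top_n=40, n_perm=150, seed=0)
        within = [sim.loc["A0", "A1"], sim.loc["B0", "B1"]]
        across = [sim.loc["A0", "B0"], sim.loc["A1", "B2"]]
        assert min(within) > max(across)
        assert np.allclose(sim.to_numpy(), sim.to_numpy().T)

    def test_consensus_recovers_planted_groups(self):
        profiles = _mechanism_profiles()
        sim = similarity_matrix(profiles, top_n=40, n_perm=150, seed=0)
        labels, consensus = consensus_cluster(sim, k=2, n_resamples=40, seed=0)
        a = set(labels[[d for d in labels.index if d.startswith("A")]])
        b = set(labels[[d for d in labels.index if d.startswith("B")]])
        assert len(a) == 1 and len(b) == 1 and a != b
        c = consensus.to_numpy()
        assert c.min() >= 0.0 and c.max() <= 1.0

    def test_same_seed_reproducible(self):
        profiles = _mechanism_profiles()
        sim = similarity_matrix(profiles, top_n=40, n_perm=100, seed=3)
        l1, _ = consensus_cluster(sim, k=2, n_resamples=20, seed=9)
        l2, _ = consensus_cluster(sim, k=2, n_resamples=20, seed=9)
        assert l1.equals(l2)

    def test_k_exceeding_drugs_rejected(self):
        sim = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="exceeds"):
            consensus_cluster(sim, k=5)


class TestAnticorrelatedPairs:
    def test_negated_drug_pair_kept(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=40)
        pic50 = pd.DataFrame(
            {"p%d" % i: [base[i], -base[i], rng.normal()] for i in range(40)},
            index=["d1", "d2", "d3"],
        )
        kept = anticorrelated_pairs(pic50)
        pairs = set(map(tuple, kept[["drug_a", "drug_b"]].to_numpy()))
        assert ("d1", "d2") in pairs
        assert kept.set_index(["drug_a", "drug_b"]).loc[("d1", "d2"), "rho"] == pytest.approx(-1.0)

    def test_threshold_is_on_r_not_only_p(self):
        """rho = -0.29 is excluded however significant."""
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.normal(size=n)
        y = -0.3 * x + rng.normal(size=n)  # |rho| just under 0.3
        pic50 = pd.DataFrame([x, y], index=["d1", "d2"],
                             columns=[f"p{i}" for i in range(n)])
        kept = anticorrelated_pairs(pic50, r_max=-0.3)
        from scipy.stats import spearmanr
        rho = spearmanr(x, y).statistic
        if rho > -0.3:  # guard: construction keeps rho just above the cut
            assert kept.empty

    def test_independent_drugs_rarely_kept(self):
        rng = np.random.default_rng(4)
        pic50 = pd.DataFrame(rng.normal(size=(8, 60)),
                             index=[f"d{i}" for i in range(8)],
                             columns=[f"p{i}" for i in range(60)])
        kept = anticorrelated_pairs(pic50)
        assert len(kept) == 0

    def test_too_few_patients_rejected(self):
        pic50 = pd.DataFrame(np.zeros((2, 5)))
        with pytest.raises(ValueError):
            anticorrelated_pairs(pic50)
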