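import numpy as np
import pandas as pd
import pytest

from conftest import binom_sf_enumerated
from topeseq._util import AA_ALPHABET
from topeseq.motif import (
    MotifError,
    PeptideHit,
    annotate_recurrence,
    baseline_significance,
    binding_filter,
    extract_kmers,
    gibbs_cluster,
    motif_matrix,
    random_peptides,
    recurrence_test,
    select_k,
)
from topeseq.simulate import toy_binding_rank, toy_rank_table

LOG2_20 = np.log2(20.0)


def plant_motif(core, n, rng, variable_positions=(4,)):
    """Peptides sharing a conserved core with a few free positions."""
    out = []
    for _ in range(n):
        p = list(core)
        for vp in variable_positions:
            p[vp] = AA_ALPHABET[rng.integers(20)]
        out.append("".join(p))
    return out


class TestExtractKmers:
    def test_hit_minigene_yields_all_kmers(self, rng):
        seq = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 60))
        assert len({seq[i:i + 9] for i in range(52)}) == 52  # all distinct
        peps = extract_kmers({"m1": seq}, {"m1": (3.0, True)}, 9)
        assert len(peps) == 52  # 60 - 9 + 1

    def test_provenance_spans_non_hits(self):
        pep = "WYVTSRQPN"
        mg = {"hit": "AAAA" + pep + "CCCC", "bg1": pep + "DDDDDDDD",
              "bg2": "EEEEEEEE" + pep}
        sig = {"hit": (3.0, True), "bg1": (0.1, False), "bg2": (0.0, False)}
        peps = extract_kmers(mg, sig, 9)
        rec = next(p for p in peps if p.peptide == pep)
        assert rec.n_sources == 3 and rec.n_significant == 1

    def test_no_hits_empty(self):
        assert extract_kmers({"m": "ACDEFGHIKL"}, {"m": (0.0, False)}, 9) == []


class TestRecurrenceTest:
    def test_worked_example(self):
        assert recurrence_test(5, 3, 0.1) == pytest.approx(0.00856, abs=5e-5)

    def test_boundaries(self):
        assert recurrence_test(5, 0, 0.1) == pytest.approx(1.0)
        assert recurrence_test(3, 3, 0.5) == pytest.approx(0.125)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 13))
            s = int(rng.integers(0, m + 1))
            q = float(rng.uniform(0.01, 0.99))
            assert recurrence_test(m, s, q) == pytest.approx(
                binom_sf_enumerated(s, m, q), rel=1e-9)

    def test_invalid_q_rejected(self):
        with pytest.raises(MotifError):
            recurrence_test(5, 2, 0.0)

    def test_single_source_bypasses(self):
        hits = [PeptideHit("AAAAAAAAA", (("m", 3.0, True),))]
        annotate_recurrence(hits, 0.05)
        assert hits[0].recurrence_p is None


class TestBindingFilter:
    def peptide(self, seq, hit=True):
        return PeptideHit(seq, (("m_" + seq, 2.0, hit),))

    def test_strict_cutoff_boundary(self):
        peps = [self.peptide("A" * 9), self.peptide("C" * 9)]
        table = pd.DataFrame({"peptide": ["A" * 9, "C" * 9],
                              "allele": "X", "rank": [4.9, 5.0]})
        kept, _ = binding_filter(peps, table, cutoff=5)
        assert [p.peptide for p in kept] == ["A" * 9]
        assert kept[0].binding_rank == 4.9

    def test_missing_peptides_removed_with_report(self):
        peps = [self.peptide("A" * 9)]
        kept, rep = binding_filter(peps, {"OTHER": 1.0})
        assert kept == [] and rep["n_missing_from_table"] == 1

    def test_huge_cutoff_is_identity(self):
        peps = [self.peptide("A" * 9), self.peptide("C" * 9)]
        kept, rep = binding_filter(peps, {"A" * 9: 99, "C" * 9: 50}, cutoff=100)
        assert len(kept) == 2

    def test_empty_table_rejected(self):
        with pytest.raises(MotifError):
            binding_filter([self.peptide("A" * 9)], {})

    def test_toy_rank_table_matches_predictor(self):
        peps = ["ASDFGHKLY", "AADFGHKLA"]
        t = toy_rank_table(peps)
        assert list(t["rank"]) == [toy_binding_rank(p) for p in peps]
        assert t["rank"].iloc[0] < 5 <= t["rank"].iloc[1]


class TestGibbsCluster:
    def test_pure_cluster_closed_form(self):
        sol = gibbs_cluster(["EVDPIGHLY"] * 30, 1, seed=0, pseudocount=0.0,
                            trash_threshold=-1e9, n_restarts=1)
        assert sol.clusters[0].kld == pytest.approx(9 * LOG2_20, abs=1e-9)

    def test_uniform_random_kld_near_zero(self, rng):
        peps = random_peptides(400, 9, rng)
        sol = gibbs_cluster(peps, 1, seed=0, trash_threshold=-1e9, n_restarts=1)
        assert abs(sol.clusters[0].kld) < 2.0

    def test_adding_random_peptide_lowers_pure_kld(self, rng):
        pure = ["EVDPIGHLY"] * 20
        base = gibbs_cluster(pure, 1, seed=0, trash_threshold=-1e9,
                             n_restarts=1).clusters[0].kld
        mixed = gibbs_cluster(pure + ["".join(AA_ALPHABET[i] for i in
                                              rng.integers(0, 20, 9))], 1,
                              seed=0, trash_threshold=-1e9,
                              n_restarts=1).clusters[0].kld
        assert mixed < base

    def test_two_planted_motifs_recovered(self, rng):
        a = plant_motif("EVDPIGHLY", 15, rng)
        b = plant_motif("KKLRWTSNA", 15, rng)
        sol = gibbs_cluster(a + b, 2, seed=0)
        assert len(sol.clusters) == 2
        for c in sol.clusters:
            firsts = {m[0] for m in c.members}
            assert firsts <= {"E"} or firsts <= {"K"}  # no mixing
        recovered = sum(len(c.members) for c in sol.clusters)
        assert recovered / 30 > 0.9

    def test_kld_invariant_under_reordering(self, rng):
        peps = plant_motif("EVDPIGHLY", 20, rng)
        a = gibbs_cluster(peps, 1, seed=3, n_restarts=1)
        b = gibbs_cluster(peps[::-1], 1, seed=3, n_restarts=1)
        assert a.clusters[0].kld == pytest.approx(b.clusters[0].kld, abs=1e-9)

    def test_deterministic_for_fixed_seed(self, rng):
        peps = plant_motif("EVDPIGHLY", 12, rng) + random_peptides(20, 9, rng)
        s1 = gibbs_cluster(peps, 2, seed=11)
        s2 = gibbs_cluster(peps, 2, seed=11)
        assert [c.members for c in s1.clusters] == [c.members for c in s2.clusters]

    def test_too_few_peptides_rejected(self):
        with pytest.raises(MotifError):
            gibbs_cluster(["AAAA"], 2, seed=0)


class TestSelectK:
    def test_single_motif_prefers_one_cluster(self, rng):
        peps = plant_motif("EVDPIGHLY", 30, rng)
        sol = select_k(peps, k_range=range(1, 4), seed=0)
        assert len(sol.clusters) == 1

    def test_two_motifs_prefer_two_clusters(self, rng):
        peps = (plant_motif("EVDPIGHLY", 20, rng)
                + plant_motif("KKLRWTSNA", 20, rng))
        sol = select_k(peps, k_range=range(1, 4), seed=0)
        assert len(sol.clusters) == 2

    def test_trivial_range_returns_k1(self, rng):
        peps = plant_motif("EVDPIGHLY", 10, rng)
        sol = select_k(peps, k_range=range(1, 2), seed=0)
        assert sol.n_clusters == 1


class TestBaseline:
    def test_planted_cluster_significant_vs_anchored_baseline(self, rng):
        # both arms share the synthetic anchor filter, as in a rank-filtered
        # screen: the planted motif must stand out above chance cliques
        planted = plant_motif("ESDPIVAQY", 20, rng, variable_positions=(4, 5))
        background = random_peptides(80, 9, rng, rank_fn=toy_binding_rank)
        sol = select_k(planted + background, k_range=range(1, 4), seed=2)
        sol, base = baseline_significance(
            sol, n_iterations=5, seed=3, k_range=range(1, 4),
            rank_fn=toy_binding_rank)
        assert base.sd > 0 and base.scores.size >= 2
        top = max(sol.clusters, key=lambda c: c.kld)
        n_planted = sum(1 for m in top.members if m.startswith("ESDP"))
        assert n_planted >= 0.8 * 20
        assert top.baseline_p < 0.01

    def test_cluster_at_baseline_mean_gets_p_half(self, rng):
        # low trash threshold so every run yields clusters: this checks the
        # one-sample Z arithmetic, not the pruning policy
        peps = random_peptides(60, 9, rng, rank_fn=toy_binding_rank)
        sol = select_k(peps, k_range=range(1, 3), seed=5, trash_threshold=4.0)
        sol, base = baseline_significance(sol, n_iterations=4, seed=6,
                                          k_range=range(1, 3),
                                          rank_fn=toy_binding_rank,
                                          trash_threshold=4.0)
        for c in sol.clusters:
            if abs(c.kld - base.mean) < 1e-9:
                assert c.baseline_p == pytest.approx(0.5)
            assert c.baseline_z == pytest.approx((c.kld - base.mean) / base.sd)


class TestMotifMatrix:
    def test_single_member_one_hot(self):
        sol = gibbs_cluster(["ACDEF"] * 3, 1, seed=0, trash_threshold=-1e9)
        counts, freqs, members = motif_matrix(sol.clusters[0])
        assert np.allclose(freqs.sum(axis=0), 1.0)
        assert freqs.loc["A", 1] == 1.0 and freqs.loc["F", 5] == 1.0

    def test_half_frequencies_at_variable_column(self):
        sol = gibbs_cluster(["ACDEF", "AGDEF"] * 3, 1, seed=0,
                            trash_threshold=-1e9)
        _, freqs, _ = motif_matrix(sol.clusters[0])
        assert freqs.loc["C", 2] == pytest.approx(0.5)
        assert freqs.loc["G", 2] == pytest.approx(0.5)

    def test_members_ranked_by_rf_score(self):
        sol = gibbs_cluster(["ACDEF", "AGDEF"] * 3, 1, seed=0,
                            trash_threshold=-1e9)
        _, _, members = motif_matrix(sol.clusters[0],
                                     rf_scores={"ACDEF": 0.2, "AGDEF": 0.9})
        assert members[0] == "AGDEF"
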