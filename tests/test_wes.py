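import numpy as np
import pytest

from topeseq._util import reverse_complement, translate
from topeseq.quant import QuantError
from topeseq.simulate import (
    Fragment,
    SimConfig,
    inserts_to_sam,
    make_toy_genome,
    simulate_wes_inserts,
)
from topeseq.wes import (
    FWD,
    REV,
    AnnotationError,
    CodingSegment,
    InsertRecord,
    PeptideWindow,
    count_in_frame,
    count_in_frame_bruteforce,
    enumerate_windows,
    infer_inserts,
    window_scores,
)


def make_window(w_start, k=9, contig="chr1", strand="+"):
    return PeptideWindow(contig, strand, w_start, w_start + 3 * k, k, "A" * k)


class TestEnumerateWindows:
    def test_window_counts_per_k(self, toy_genome):
        genome, segs = toy_genome
        seg = [segs[0]]
        assert len(enumerate_windows(seg, genome, 9)) == 22   # 30 - 9 + 1
        assert len(enumerate_windows(seg, genome, 8)) == 23   # 30 - 8 + 1

    def test_too_short_segment_yields_nothing(self):
        genome = {"c": "ATG" * 8}
        seg = [CodingSegment("c", 0, 24, "+")]
        assert enumerate_windows(seg, genome, 9) == []

    def test_minus_strand_translates_reverse_complement(self):
        pep = "MKLVNQWER"
        from topeseq.design import back_translate
        coding = back_translate(pep, 4, forbidden_motifs=())
        genome = {"c": "ACGT" * 5 + reverse_complement(coding) + "ACGT" * 5}
        seg = [CodingSegment("c", 20, 20 + 27, "-")]
        wins = enumerate_windows(seg, genome, 9)
        assert len(wins) == 1
        assert wins[0].peptide == pep

    def test_stop_containing_windows_dropped(self):
        # one codon in annotated frame is a stop: every window spanning it dies
        genome = {"c": "ATG" * 10 + "TAA" + "ATG" * 10}
        seg = [CodingSegment("c", 0, 63, "+")]
        wins = enumerate_windows(seg, genome, 9)
        assert all("*" not in w.peptide for w in wins)
        # 21 codons, 13 candidate starts, those overlapping codon 10 dropped
        assert len(wins) == 13 - 9

    def test_duplicate_segments_deduplicated(self, toy_genome):
        genome, segs = toy_genome
        once = enumerate_windows([segs[0]], genome, 9)
        twice = enumerate_windows([segs[0], segs[0]], genome, 9)
        assert once == twice

    def test_segment_past_contig_end_errors(self):
        with pytest.raises(AnnotationError):
            enumerate_windows([CodingSegment("c", 0, 33, "+")], {"c": "ATG" * 5}, 9)


class TestCountInFrame:
    def test_congruence_examples(self):
        ins = [InsertRecord("chr1", 100, 340, FWD)]
        counted = make_window(103)
        shifted = make_window(104)
        not_spanning = make_window(103)
        assert count_in_frame(ins, [counted])[0] == 1
        assert count_in_frame(ins, [shifted])[0] == 0
        assert count_in_frame([InsertRecord("chr1", 110, 130, FWD)],
                              [not_spanning])[0] == 0

    def test_six_expression_states_exactly_one_congruent(self):
        # a fragment cloned in each orientation x offset state over one CDS
        window = make_window(103)
        states = [InsertRecord("chr1", 100 + off, 340 + off, orient)
                  for orient in (FWD, REV) for off in (0, 1, 2)]
        assert len(states) == 6
        hits = [int(count_in_frame([s], [window])[0]) for s in states]
        assert sum(hits) == 1  # only fwd, offset 0 is congruent with w_start 103
        minus_window = PeptideWindow("chr1", "-", 103, 130, 9, "A" * 9)
        hits_minus = [int(count_in_frame([s], [minus_window])[0]) for s in states]
        assert sum(hits_minus) == 1

    def test_monotone_in_inserts(self, rng):
        windows = [make_window(s) for s in range(90, 140)]
        inserts = []
        prev = np.zeros(len(windows))
        for _ in range(20):
            a = int(rng.integers(0, 200))
            inserts.append(InsertRecord("chr1", a, a + int(rng.integers(60, 300)),
                                        FWD if rng.random() < 0.5 else REV))
            cur = count_in_frame(inserts, windows)
            assert (cur >= prev).all()
            prev = cur

    def test_matches_bruteforce_oracle(self, rng):
        windows = []
        for _ in range(200):
            k = int(rng.integers(8, 12))
            strand = "+" if rng.random() < 0.5 else "-"
            w = int(rng.integers(0, 500))
            windows.append(PeptideWindow("chr1", strand, w, w + 3 * k, k, "A" * k))
        inserts = []
        for _ in range(50):
            a = int(rng.integers(0, 500))
            inserts.append(InsertRecord("chr1", a, a + int(rng.integers(30, 400)),
                                        FWD if rng.random() < 0.5 else REV))
        for off in (0, 1, 2):
            fast = count_in_frame(inserts, windows, frame_offset=off)
            slow = count_in_frame_bruteforce(inserts, windows, frame_offset=off)
            assert (fast == slow).all()

    def test_require_open_frame_drops_interrupted_inserts(self):
        # insert starts upstream of a stop codon in its expressed frame
        genome = {"c": "ATG" * 5 + "TAA" + "ATG" * 20}
        window = PeptideWindow("c", "+", 18 + 9, 18 + 9 + 27, 9, "M" * 9)
        ins_through_stop = [InsertRecord("c", 0, 78, FWD)]
        ins_after_stop = [InsertRecord("c", 18, 78, FWD)]
        assert count_in_frame(ins_through_stop, [window])[0] == 1  # literal mode
        assert count_in_frame(ins_through_stop, [window],
                              require_open_frame=True, genome=genome)[0] == 0
        assert count_in_frame(ins_after_stop, [window],
                              require_open_frame=True, genome=genome)[0] == 1


class TestInferInserts:
    def test_round_trip_through_sam(self, toy_genome, tmp_path, rng):
        genome, _ = toy_genome
        want = []
        for _ in range(30):
            a = int(rng.integers(0, 150))
            b = a + int(rng.integers(150, 250))
            want.append(InsertRecord("chr1", a, b,
                                     FWD if rng.random() < 0.5 else REV))
        sam = inserts_to_sam(want, genome, tmp_path / "x.sam")
        got, stats = infer_inserts(sam, min_mapq=20)
        assert sorted(got, key=str) == sorted(want, key=str)
        assert stats["retained"] == 30

    def test_mapq_and_duplicate_filters(self, toy_genome, tmp_path):
        import pysam
        genome, _ = toy_genome
        ins = [InsertRecord("chr1", 10, 200, FWD)]
        sam = inserts_to_sam(ins, genome, tmp_path / "f.sam")
        # rewrite with low mapq / duplicate flags
        recs = list(pysam.AlignmentFile(str(sam)))
        for variant, mutate in (("lowq", "mapq"), ("dup", "dup")):
            path = tmp_path / f"{variant}.sam"
            with pysam.AlignmentFile(str(path), "wh",
                                     template=pysam.AlignmentFile(str(sam))) as out:
                for r in recs:
                    if mutate == "mapq":
                        r.mapping_quality = 5
                    else:
                        r.is_duplicate = True
                    out.write(r)
            got, stats = infer_inserts(path, min_mapq=20)
            assert got == []


class TestWindowScores:
    def test_single_window_normalizes_to_million(self):
        w = [make_window(90)]
        table = window_scores({("R1", "Shifted"): np.array([5]),
                               ("R1", "Unshifted"): np.array([4])}, w)
        assert (table.norm_count == 1e6).all()

    def test_zero_depth_gate_errors(self):
        with pytest.raises(QuantError):
            window_scores({("R1", "Shifted"): np.array([0])}, [make_window(90)])

    def test_peptide_collapsed_view_sums_loci(self):
        wins = [PeptideWindow("chr1", "+", 0, 27, 9, "SAMEPEPTI"),
                PeptideWindow("chr1", "+", 30, 57, 9, "SAMEPEPTI")]
        t = window_scores({("R1", "Shifted"): np.array([2, 3]),
                           ("R1", "Unshifted"): np.array([1, 1])},
                          wins, collapse_peptides=True)
        s = t[(t.gate == "Shifted")]
        assert len(s) == 1 and s.iloc[0].raw_count == 5

    def test_planted_epitope_window_tops_ranking(self):
        from topeseq.enrichment import score_screen
        genome, segs = make_toy_genome(n_contigs=1, segments_per_contig=12,
                                       codons_per_segment=40, seed=8)
        windows = enumerate_windows(segs, genome, 9)
        planted = windows[40]
        cfg = SimConfig(seed=0, n_founder_cells=30_000, read_depth=150_000,
                        shift_prob_background=0.0005)
        samples, _frags = simulate_wes_inserts(
            genome, [(planted, 0.9)], cfg, n_fragments=4000)
        counts = {key: count_in_frame(ins, windows)
                  for key, ins in samples.items()}
        scored = score_screen(window_scores(counts, windows))
        assert scored.iloc[0].entity_id == planted.locus_id
        assert scored.iloc[0].percentile > 99
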