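"""In-frame peptide window counting for shotgun (WES-style) minigene libraries.

Shotgun fragments are cloned without frame control, so a fragment expresses a
peptide in one of six states (two orientations x three codon offsets).  The
analysis therefore scores peptide *loci* rather than fragments: every k-mer
(k = 8..11 residues) window of the annotated coding genome is enumerated in
its annotated frame, and a sequenced insert counts toward a window iff it
fully traverses the window, is cloned in the window's orientation, and its
expression frame is congruent with the window frame.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._util import reverse_complement, translate

FWD, REV = "fwd", "rev"


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class CodingSegment:
    contig: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str  # '+' or '-'
    phase: int = 0  # bases to skip from the segment's 5' end to the first codon

    def __post_init__(self):
        if self.start >= self.end:
            raise AnnotationError(f"empty segment {self}")
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r}")
        if not 0 <= self.phase <= 2:
            raise AnnotationError(f"bad phase {self.phase}")

    @property
    def frame_anchor(self) -> int:
        """Genomic coordinate of the first base of an in-frame codon:
        for '+' the first codon start; for '-' the exclusive end of the
        5'-most codon (codons run right to left)."""
        return self.start + self.phase if self.strand == "+" else self.end - self.phase


@dataclass(frozen=True)
class PeptideWindow:
    contig: str
    strand: str
    w_start: int  # genomic half-open span, w_end - w_start == 3k
    w_end: int
    k: int
    peptide: str

    @property
    def locus_id(self) -> str:
        return f"{self.contig}:{self.strand}:{self.w_start}:{self.k}"


@dataclass(frozen=True)
class InsertRecord:
    contig: str
    a: int  # half-open genomic insert span
    b: int
    orientation: str  # expressed strand of the cloned fragment: 'fwd'/'rev'


def read_segments(path) -> list[CodingSegment]:
    """Read a CDS segment TSV: contig, start, end, strand, phase (comments '#')."""
    segs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("contig\t"):
                continue
            contig, start, end, strand, phase = line.split("\t")[:5]
            segs.append(CodingSegment(contig, int(start), int(end), strand, int(phase)))
    return segs


def enumerate_windows(segments, genome, k: int) -> list[PeptideWindow]:
    """Enumerate all stop-free in-frame k-mer peptide windows within segments.

    ``genome`` maps contig -> sequence.  Windows are deduplicated by
    (contig, strand, w_start, k); windows whose translation contains a stop
    are dropped.
    """
    seen, out = set(), []
    for seg in segments:
        try:
            contig_seq = genome[seg.contig]
        except KeyError:
            raise AnnotationError(f"contig {seg.contig!r} absent from genome")
        if seg.end > len(contig_seq):
            raise AnnotationError(f"segment {seg} extends past contig end")
        span = 3 * k
        if seg.strand == "+":
            w = seg.frame_anchor
            while w + span <= seg.end:
                key = (seg.contig, "+", w, k)
                if key not in seen:
                    seen.add(key)
                    pep = translate(contig_seq[w:w + span])
                    if "*" not in pep:
                        out.append(PeptideWindow(seg.contig, "+", w, w + span, k, pep))
                w += 3
        else:
            w_end = seg.frame_anchor
            while w_end - span >= seg.start:
                key = (seg.contig, "-", w_end - span, k)
                if key not in seen:
                    seen.add(key)
                    pep = translate(reverse_complement(contig_seq[w_end - span:w_end]))
                    if "*" not in pep:
                        out.append(PeptideWindow(seg.contig, "-", w_end - span,
                                                 w_end, k, pep))
                w_end -= 3
    out.sort(key=lambda w: (w.contig, w.strand, w.w_start, w.k))
    return out


def infer_inserts(alignments, min_mapq: int = 20, drop_duplicates: bool = True):
    """Infer cloned-insert spans from proper read pairs.

    ``alignments`` is a SAM/BAM path or an open pysam.AlignmentFile.  One
    InsertRecord is produced per retained proper pair (from its read-1
    record): span = [leftmost start, leftmost start + |TLEN|), orientation =
    the strand of read 1, whose sequencing adapter marks the insert 5' end.

    Returns (inserts, stats).
    """
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        close = True
    inserts, stats = [], Counter()
    try:
        for aln in alignments:
            stats["records"] += 1
            if aln.is_secondary or aln.is_supplementary or not aln.is_read1:
                continue
            stats["pairs"] += 1
            if aln.is_unmapped or aln.mate_is_unmapped:
                stats["orphan"] += 1
                continue
            if not aln.is_proper_pair:
                stats["not_proper"] += 1
                continue
            if aln.mapping_quality < min_mapq:
                stats["low_mapq"] += 1
                continue
            if drop_duplicates and aln.is_duplicate:
                stats["duplicate"] += 1
                continue
            tlen = abs(aln.template_length)
            if tlen == 0:
                stats["no_tlen"] += 1
                continue
            a = min(aln.reference_start, aln.next_reference_start)
            inserts.append(InsertRecord(
                aln.reference_name, a, a + tlen,
                REV if aln.is_reverse else FWD))
            stats["retained"] += 1
    finally:
        if close:
            alignments.close()
    return inserts, dict(stats)


def _stop_codon_starts(genome) -> dict:
    """Genomic start positions of stop codons per (contig, strand, frame class).

    For '+', frame class = codon start mod 3 with codons read left to right;
    for '-', class = codon *end* (exclusive) mod 3 with codons read right to
    left on the reverse complement.
    """
    stops = {"TAA", "TAG", "TGA"}
    out: dict = defaultdict(list)
    for contig, seq in genome.items():
        for i in range(len(seq) - 2):
            cod = seq[i:i + 3]
            if cod in stops:
                out[(contig, FWD, i % 3)].append(i)
            if reverse_complement(cod) in stops:
                out[(contig, REV, (i + 3) % 3)].append(i)
    return {k: sorted(v) for k, v in out.items()}


def count_in_frame(inserts, windows, frame_offset: int = 0,
                   require_open_frame: bool = False, genome=None) -> np.ndarray:
    """Count inserts traversing each window in the congruent expression state.

    An insert (a, b, orientation) counts toward window W iff it fully contains
    W's span, its orientation matches W's strand, and the frame is congruent:
    for fwd/+, (w_start - a) mod 3 == frame_offset; for rev/-,
    (b - w_end) mod 3 == frame_offset.  With ``require_open_frame`` the
    expressed frame must additionally be stop-free from the insert 5' end to
    the window end (needs ``genome``).

    Returns an int array aligned with ``windows``.
    """
    if require_open_frame and genome is None:
        raise ValueError("require_open_frame needs the genome sequences")
    stop_index = _stop_codon_starts(genome) if require_open_frame else {}

    # bucket inserts by (contig, orientation, frame class of the 5' end)
    buckets: dict = defaultdict(lambda: ([], []))
    for ins in inserts:
        if ins.orientation == FWD:
            key = (ins.contig, FWD, ins.a % 3)
        else:
            key = (ins.contig, REV, ins.b % 3)
        buckets[key][0].append(ins.a)
        buckets[key][1].append(ins.b)
    buckets = {k: (np.asarray(a), np.asarray(b)) for k, (a, b) in buckets.items()}

    counts = np.zeros(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        if w.strand == "+":
            key = (w.contig, FWD, (w.w_start - frame_offset) % 3)
        else:
            key = (w.contig, REV, (w.w_end + frame_offset) % 3)
        if key not in buckets:
            continue
        A, B = buckets[key]
        mask = (A <= w.w_start) & (B >= w.w_end)
        if require_open_frame and mask.any():
            orient = FWD if w.strand == "+" else REV
            stops = stop_index.get((w.contig, orient, key[2]), [])
            if stops:
                idx = np.flatnonzero(mask)
                for j in idx:
                    if orient == FWD:
                        # stop codon [t, t+3) wholly inside [a, w_end)?
                        p = bisect_left(stops, int(A[j]))
                        if p < len(stops) and stops[p] + 3 <= w.w_end:
                            mask[j] = False
                    else:
                        # expressed 5' end is b; stop [t, t+3) inside [w_start, b)
                        p = bisect_left(stops, w.w_start)
                        if p < len(stops) and stops[p] + 3 <= int(B[j]):
                            mask[j] = False
        counts[i] = int(mask.sum())
    return counts


def count_in_frame_bruteforce(inserts, windows, frame_offset: int = 0) -> np.ndarray:
    """Quadratic all-pairs reference implementation (testing oracle)."""
    counts = np.zeros(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        for ins in inserts:
            if ins.contig != w.contig:
                continue
            if not (ins.a <= w.w_start and w.w_end <= ins.b):
                continue
            if w.strand == "+" and ins.orientation == FWD:
                if (w.w_start - ins.a) % 3 == frame_offset % 3:
                    counts[i] += 1
            elif w.strand == "-" and ins.orientation == REV:
                if (ins.b - w.w_end) % 3 == frame_offset % 3:
                    counts[i] += 1
    return counts


def window_scores(sample_counts: dict, windows, collapse_peptides: bool = False
                  ) -> pd.DataFrame:
    """Per-window normalized counts in GateCounts form.

    ``sample_counts`` maps (replicate, gate) -> count array aligned with
    ``windows``.  Entities are keyed by genomic locus; with
    ``collapse_peptides`` counts of identical peptide strings are summed and
    keyed by peptide instead.
    """
    from .quant import QuantError, build_count_table

    table = {}
    for key, arr in sample_counts.items():
        arr = np.asarray(arr)
        if arr.sum() <= 0:
            raise QuantError(f"gate sample {key} has zero depth")
        counts: Counter = Counter()
        for w, c in zip(windows, arr):
            if c > 0:
                entity = w.peptide if collapse_peptides else w.locus_id
                counts[entity] += int(c)
        table[key] = counts
    return build_count_table(table)


def quantify_wes(bam_by_sample: dict, segments, genome, ks=(8, 9, 10, 11),
                 frame_offset: int = 0, min_mapq: int = 20,
                 require_open_frame: bool = False, out_dir=None):
    """Full WES quantification: inserts -> windows -> in-frame counts.

    ``bam_by_sample`` maps (replicate, gate) -> SAM/BAM path.  Returns
    (windows, counts table, stats).
    """
    windows = []
    for k in ks:
        windows.extend(enumerate_windows(segments, genome, k))
    sample_counts, stats = {}, {}
    for key, path in sorted(bam_by_sample.items()):
        inserts, st = infer_inserts(path, min_mapq=min_mapq)
        sample_counts[key] = count_in_frame(
            inserts, windows, frame_offset=frame_offset,
            require_open_frame=require_open_frame, genome=genome)
        stats[f"{key[0]}/{key[1]}"] = st
    table = window_scores(sample_counts, windows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "windows.tsv", "w") as fh:
            fh.write("# locus_id\tcontig\tstrand\tw_start\tw_end\tk\tpeptide\n")
            for w in windows:
                fh.write(f"{w.locus_id}\t{w.contig}\t{w.strand}\t{w.w_start}\t"
                         f"{w.w_end}\t{w.k}\t{w.peptide}\n")
        with open(out / "counts.tsv", "w") as fh:
            fh.write("# entity_id\treplicate\tgate\traw_count\t"
                     "norm_count (reads per million in sample)\n")
            table.to_csv(fh, sep="\t", index=False)
    return windows, table, stats
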