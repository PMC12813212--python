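"""Per-minigene read quantification for WPC sort-seq screens.

Amplicon paired-end reads from each FACS gate are adapter-trimmed and
quality-filtered, overlap-merged into full-length inserts, collapsed into
error-corrected centroids by greedy Levenshtein sphere clustering, assigned
to the designed reference minigenes within a bounded edit distance, and
tabulated as raw and depth-normalized (reads-per-million) counts per
(replicate, gate) sample.

Defaults mirror common amplicon practice: merge overlap in [20, 150] with
mismatch density <= 0.2 and read-through ("outie") geometry allowed; quality
filter keeps reads with >= 90% of bases above Q20; sphere collapse at edit
distance 4 and design assignment at edit distance 3.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import edlib
import pandas as pd

from ._util import reverse_complement

UNASSIGNED = "UNASSIGNED"


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class MergedRead:
    sequence: str
    quality: tuple[int, ...]
    overlap_len: int
    mismatches_in_overlap: int


@dataclass(frozen=True)
class Assignment:
    read_id: str
    minigene_id: str  # UNASSIGNED when no unique design within distance
    edit_distance: int
    ambiguous: bool = False


def levenshtein(a: str, b: str, k: int | None = None) -> int:
    """Levenshtein distance via edlib; returns k+1 if the distance exceeds k."""
    res = edlib.align(a, b, task="distance", k=-1 if k is None else k)
    d = res["editDistance"]
    return (k + 1) if d == -1 else d


# ---------------------------------------------------------------------------
# FASTQ I/O and pre-processing


def read_fastq(path):
    """Yield (read_id, sequence, phred_list) from a FASTQ (optionally gzipped)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                return
            seq = fh.readline().rstrip()
            fh.readline()
            qual = fh.readline().rstrip()
            if len(seq) != len(qual):
                raise QuantError(f"length/quality mismatch for {header}")
            yield header[1:].split()[0], seq, [ord(c) - 33 for c in qual]


def trim_adapter(seq: str, quals, adapter: str, min_match: int = 5):
    """Trim a 3' adapter: cut at the leftmost position where the read suffix
    exactly matches a prefix of the adapter (full internal occurrences
    included)."""
    i = seq.find(adapter)
    if i >= 0:
        return seq[:i], quals[:i]
    # partial adapter running off the 3' end
    max_ov = min(len(adapter) - 1, len(seq))
    for ov in range(max_ov, min_match - 1, -1):
        if seq.endswith(adapter[:ov]):
            return seq[:-ov], quals[:-ov]
    return seq, quals


def passes_quality(quals, q: int = 20, frac: float = 0.9) -> bool:
    """Keep a read iff at least ``frac`` of its bases exceed quality ``q``."""
    if not len(quals):
        return False
    return sum(1 for x in quals if x > q) / len(quals) >= frac


def trim_and_filter(pairs, adapter_seqs=(), q: int = 20, frac: float = 0.9):
    """Adapter-trim and quality-filter read pairs.

    ``pairs`` yields (pair_id, seq1, qual1, seq2, qual2).  Returns the list of
    passing (possibly trimmed) pairs and a stats dict.
    """
    kept, stats = [], Counter()
    for pair_id, s1, q1, s2, q2 in pairs:
        stats["input"] += 1
        if len(s1) != len(q1) or len(s2) != len(q2):
            stats["malformed"] += 1
            continue
        for ad in adapter_seqs:
            s1, q1 = trim_adapter(s1, q1, ad)
            s2, q2 = trim_adapter(s2, q2, ad)
        if passes_quality(q1, q, frac) and passes_quality(q2, q, frac):
            kept.append((pair_id, s1, q1, s2, q2))
            stats["kept"] += 1
        else:
            stats["quality_failed"] += 1
    return kept, dict(stats)


# ---------------------------------------------------------------------------
# Overlap merging


def _overlap_mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def merge_pairs(seq1, qual1, seq2, qual2, min_overlap: int = 20,
                max_overlap: int = 150, max_mm_density: float = 0.2,
                allow_outies: bool = True):
    """Overlap-merge a trimmed read pair; returns a MergedRead or None.

    Mate 2 is reverse-complemented; every candidate overlap length in
    [min_overlap, max_overlap] is scored by mismatch density in the overlap
    and the lowest-density (ties: longest) candidate wins if its density is
    <= ``max_mm_density`` (inclusive).  Disagreeing bases are resolved in
    favour of the higher-quality call.  In innie geometry the merge is
    read1 + the non-overlapping tail of mate 2; in outie (read-through)
    geometry the mates overhang each other's 5' ends and the merge is the
    overlap consensus plus both overhangs on the mate-2 side.
    """
    rc2 = reverse_complement(seq2)
    rq2 = list(qual2)[::-1]
    n1, n2 = len(seq1), len(rc2)

    best = None  # (density, ov, geometry)
    hi = min(max_overlap, n1, n2)
    for ov in range(min_overlap, hi + 1):
        mm = _overlap_mismatches(seq1[n1 - ov:], rc2[:ov])
        dens = mm / ov
        if dens <= max_mm_density:
            cand = (dens, ov, "innie", mm)
            if best is None or (cand[0], -cand[1]) < (best[0], -best[1]):
                best = cand
        if allow_outies:
            mm = _overlap_mismatches(rc2[n2 - ov:], seq1[:ov])
            dens = mm / ov
            if dens <= max_mm_density:
                cand = (dens, ov, "outie", mm)
                if best is None or (cand[0], -cand[1]) < (best[0], -best[1]):
                    best = cand
    if best is None:
        return None
    dens, ov, geom, mm = best

    if geom == "innie":
        left_s, left_q = seq1[:n1 - ov], list(qual1[:n1 - ov])
        a_s, a_q = seq1[n1 - ov:], list(qual1[n1 - ov:])
        b_s, b_q = rc2[:ov], rq2[:ov]
        right_s, right_q = rc2[ov:], rq2[ov:]
    else:  # outie: rc2 lies 5' of read1
        left_s, left_q = rc2[:n2 - ov], rq2[:n2 - ov]
        a_s, a_q = rc2[n2 - ov:], rq2[n2 - ov:]
        b_s, b_q = seq1[:ov], list(qual1[:ov])
        right_s, right_q = seq1[ov:], list(qual1[ov:])

    cons_s, cons_q = [], []
    for x, qx, y, qy in zip(a_s, a_q, b_s, b_q):
        if x == y:
            cons_s.append(x)
            cons_q.append(max(qx, qy))
        elif qx >= qy:
            cons_s.append(x)
            cons_q.append(qx)
        else:
            cons_s.append(y)
            cons_q.append(qy)
    seq = left_s + "".join(cons_s) + right_s
    qual = tuple(list(left_q) + cons_q + list(right_q))
    return MergedRead(seq, qual, ov, mm)


# ---------------------------------------------------------------------------
# Sphere clustering (error collapse)


@dataclass
class Centroid:
    sequence: str
    abundance: int


def collapse_spheres(reads, d_collapse: int = 4) -> list[Centroid]:
    """Greedy abundance-descending sphere clustering.

    ``reads`` is an iterable of sequences (with multiplicity) or a mapping
    sequence -> count.  Unique sequences are visited in descending abundance
    (ties lexicographic); each joins the most abundant earlier centroid within
    Levenshtein distance ``d_collapse``, else founds a new centroid.
    """
    counts = dict(reads) if isinstance(reads, dict) else Counter(reads)
    order = sorted(counts, key=lambda s: (-counts[s], s))
    centroids: list[Centroid] = []
    for seq in order:
        for c in centroids:  # creation order == descending seed abundance
            if levenshtein(seq, c.sequence, k=d_collapse) <= d_collapse:
                c.abundance += counts[seq]
                break
        else:
            centroids.append(Centroid(seq, counts[seq]))
    return centroids


# ---------------------------------------------------------------------------
# Assignment to designed references


class DesignIndex:
    """Edit-distance search over a design reference.

    Exact matches resolve through a hash table.  Inexact queries use a
    pigeonhole k-mer prefilter: each design of length L is cut into
    ``d_assign + 1`` contiguous pieces, so any read within edit distance
    ``d_assign`` contains at least one piece verbatim, displaced by at most
    ``d_assign`` positions.  Candidates are then verified with banded edit
    distance.
    """

    def __init__(self, designs: dict[str, str], d_assign: int = 3):
        self.d = d_assign
        self.designs = dict(designs)
        self.exact: dict[str, list[str]] = defaultdict(list)
        for did, seq in self.designs.items():
            self.exact[seq].append(did)
        # piece index per design length class
        self.by_len: dict[int, dict] = {}
        npieces = d_assign + 1
        for did, seq in self.designs.items():
            L = len(seq)
            cls = self.by_len.setdefault(L, {"bounds": None, "pieces": defaultdict(set)})
            if cls["bounds"] is None:
                cuts = [round(i * L / npieces) for i in range(npieces + 1)]
                cls["bounds"] = [(cuts[i], cuts[i + 1]) for i in range(npieces)]
            for lo, hi in cls["bounds"]:
                cls["pieces"][(lo, seq[lo:hi])].add(did)

    def candidates(self, seq: str) -> set[str]:
        out: set[str] = set()
        for L, cls in self.by_len.items():
            if abs(len(seq) - L) > self.d:
                continue
            for lo, hi in cls["bounds"]:
                plen = hi - lo
                for shift in range(-self.d, self.d + 1):
                    sub = seq[lo + shift: lo + shift + plen]
                    if len(sub) == plen and lo + shift >= 0:
                        hits = cls["pieces"].get((lo, sub))
                        if hits:
                            out |= hits
        return out

    def assign(self, seq: str, read_id: str = "") -> Assignment:
        hit = self.exact.get(seq)
        if hit and len(hit) == 1:
            return Assignment(read_id, hit[0], 0)
        if hit:
            return Assignment(read_id, UNASSIGNED, 0, ambiguous=True)
        best_d, best_ids = self.d + 1, []
        for did in sorted(self.candidates(seq)):
            d = levenshtein(seq, self.designs[did], k=self.d)
            if d < best_d:
                best_d, best_ids = d, [did]
            elif d == best_d:
                best_ids.append(did)
        if best_d <= self.d and len(best_ids) == 1:
            return Assignment(read_id, best_ids[0], best_d)
        if best_d <= self.d:
            return Assignment(read_id, UNASSIGNED, best_d, ambiguous=True)
        return Assignment(read_id, UNASSIGNED, best_d)


def assign_to_design(seq, designs, d_assign: int = 3, read_id: str = "") -> Assignment:
    """Assign one sequence to the unique nearest design within ``d_assign``.

    ``designs`` may be a DesignIndex (reused across calls) or a mapping
    id -> sequence.  Equidistant nearest designs yield UNASSIGNED (ambiguous).
    """
    index = designs if isinstance(designs, DesignIndex) else DesignIndex(designs, d_assign)
    return index.assign(seq, read_id)


# ---------------------------------------------------------------------------
# Count tables


def build_count_table(sample_counts: dict) -> pd.DataFrame:
    """Build the per-(replicate, gate) count table.

    ``sample_counts`` maps (replicate_id, gate) -> {entity_id: raw_count}.
    Normalized counts are reads-per-million within each sample; a sample with
    zero assigned reads is an error.
    """
    rows = []
    for (replicate, gate), counts in sorted(sample_counts.items()):
        total = sum(counts.values())
        if total <= 0:
            raise QuantError(f"sample ({replicate}, {gate}) has no assigned reads")
        for entity, raw in sorted(counts.items()):
            rows.append((entity, replicate, gate, int(raw), raw / total * 1e6))
    return pd.DataFrame(rows, columns=["entity_id", "replicate", "gate",
                                       "raw_count", "norm_count"])


def quantify_sample(fastq1, fastq2, index: DesignIndex, adapter_seqs=None,
                    q: int = 20, frac: float = 0.9, d_collapse: int = 4):
    """FASTQ pair -> per-minigene raw counts for one (replicate, gate) sample.

    Returns (counts dict, diagnostics dict).  Unassigned/ambiguous centroid
    abundances are reported in the diagnostics but excluded from counts.
    """
    from .design import FWD_ADAPTER, REV_PRIMER_ANNEAL

    if adapter_seqs is None:
        # after merging, read-through runs into the opposite amplification
        # adapter; trim both anneal regions from raw mates
        adapter_seqs = (reverse_complement(REV_PRIMER_ANNEAL),
                        reverse_complement(FWD_ADAPTER))
    pairs = ((rid1, s1, q1, s2, q2)
             for (rid1, s1, q1), (_rid2, s2, q2)
             in zip(read_fastq(fastq1), read_fastq(fastq2)))
    kept, trim_stats = trim_and_filter(pairs, adapter_seqs, q=q, frac=frac)

    merged, n_merge_fail = [], 0
    for _pid, s1, q1, s2, q2 in kept:
        m = merge_pairs(s1, q1, s2, q2)
        if m is None:
            n_merge_fail += 1
        else:
            merged.append(m.sequence)

    centroids = collapse_spheres(merged, d_collapse=d_collapse)
    counts: Counter = Counter()
    n_unassigned = n_ambiguous = 0
    for c in centroids:
        a = index.assign(c.sequence)
        if a.minigene_id == UNASSIGNED:
            if a.ambiguous:
                n_ambiguous += c.abundance
            else:
                n_unassigned += c.abundance
        else:
            counts[a.minigene_id] += c.abundance
    n_assigned = sum(counts.values())
    n_merged = len(merged)
    diagnostics = {
        **trim_stats,
        "merged": n_merged,
        "merge_failed": n_merge_fail,
        "merge_rate": n_merged / max(1, trim_stats.get("kept", 0)),
        "centroids": len(centroids),
        "assigned": n_assigned,
        "ambiguous": n_ambiguous,
        "unassigned": n_unassigned,
        "assignment_rate": n_assigned / max(1, n_merged),
        "ambiguity_rate": n_ambiguous / max(1, n_merged),
    }
    return dict(counts), diagnostics


def quantify_wpc(reference: dict[str, str], samples: dict, out_dir=None,
                 d_assign: int = 3, **kw):
    """Quantify several (replicate, gate) FASTQ pairs against one reference.

    ``samples`` maps (replicate_id, gate) -> (fastq1, fastq2).  Writes
    counts.tsv and diagnostics.json when ``out_dir`` is given.
    """
    index = DesignIndex(reference, d_assign)
    sample_counts, diags = {}, {}
    for key, (f1, f2) in sorted(samples.items()):
        counts, diag = quantify_sample(f1, f2, index, **kw)
        sample_counts[key] = counts
        diags[f"{key[0]}/{key[1]}"] = diag
    table = build_count_table(sample_counts)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "counts.tsv", "w") as fh:
            fh.write("# entity_id\treplicate\tgate\traw_count\t"
                     "norm_count (reads per million in sample)\n")
            table.to_csv(fh, sep="\t", index=False)
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(diags, fh, indent=2)
    return table, diags
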