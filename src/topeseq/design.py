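"""Whole-proteome-coding (WPC) minigene library design.

A reference proteome is tiled into overlapping fixed-length amino-acid
fragments, exact duplicate tiles are consolidated (isoforms and paralogous
domains produce identical tiles), each unique tile is back-translated with
randomized synonymous codons, and the coding insert is flanked with the
adapter-annealing regions used for amplification and cloning.  With the
default 60-residue tiles and two 18-nt flanks every full-length member is a
216-nt oligo suitable for array synthesis.

Random (non-native) codon usage is deliberate: it prevents concatemerization
of overlapping single-stranded oligos during PCR-based pooled cloning, and it
decouples the DNA sequence of neighbouring tiles that share 30 residues of
protein sequence.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from ._util import SYNONYMOUS_CODONS, as_rng, reverse_complement, translate

#: 18-nt adapter-annealing regions used for library amplification; the
#: reverse flank is the reverse complement of the reverse primer anneal site
#: so that the primer anneals to the oligo's bottom strand.
FWD_ADAPTER = "ACGACGCTCTTCCGATCT"
REV_PRIMER_ANNEAL = "CGTGTGCTCTTCCGATCT"
REV_ADAPTER = reverse_complement(REV_PRIMER_ANNEAL)  # AGATCGGAAGAGCACACG

#: Meganuclease recognition sites used in pooled cloning; an internal
#: occurrence in a minigene would be cut during library construction.
I_SCEI_SITE = "TAGGGATAACAGGGTAAT"
PI_SCEI_SITE = "ATCTATGTCGGGTGCGGAGAAAGAGGTAAT"
DEFAULT_FORBIDDEN_MOTIFS = (I_SCEI_SITE, PI_SCEI_SITE)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class DesignError(ValueError):
    """Raised for invalid design inputs (empty sequences, malformed FASTA)."""


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise DesignError(f"protein {self.protein_id!r} has empty sequence")
        if "*" in self.sequence:
            raise DesignError(f"protein {self.protein_id!r} contains a stop symbol")


@dataclass(frozen=True)
class Tile:
    protein_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    aa_seq: str


@dataclass(frozen=True)
class ConsolidatedTile:
    """A unique tile amino-acid sequence with merged provenance."""

    aa_seq: str
    sources: tuple[tuple[str, int], ...]  # (protein_id, start)


@dataclass(frozen=True)
class MinigeneDesign:
    minigene_id: str
    aa_seq: str
    dna_seq: str
    oligo_seq: str
    sources: tuple[tuple[str, int], ...]


def tile_protein(seq: str, frag_len: int = 60, min_overlap: int = 30,
                 protein_id: str = "") -> list[Tile]:
    """Tile a protein into overlapping fragments.

    Tiles start at multiples of ``frag_len - min_overlap``; a final tile is
    anchored at ``max(0, L - frag_len)`` so the C-terminus is always covered
    and consecutive tiles overlap by at least ``min_overlap``.  Proteins
    shorter than ``frag_len`` yield a single full-length tile.
    """
    if not seq:
        raise DesignError("cannot tile an empty sequence")
    if frag_len < 1:
        raise DesignError("frag_len must be >= 1")
    if not (0 <= min_overlap < frag_len):
        raise DesignError("min_overlap must satisfy 0 <= min_overlap < frag_len")
    L = len(seq)
    if L <= frag_len:
        return [Tile(protein_id, 0, L, seq)]
    step = frag_len - min_overlap
    starts = list(range(0, L - frag_len + 1, step))
    if starts[-1] != L - frag_len:
        starts.append(L - frag_len)
    return [Tile(protein_id, s, s + frag_len, seq[s:s + frag_len]) for s in starts]


def consolidate_tiles(tiles) -> list[ConsolidatedTile]:
    """Merge tiles with identical amino-acid sequence.

    One record per distinct ``aa_seq`` with the provenance of every producing
    (protein, start); output ordered lexicographically by ``aa_seq`` so the
    library is deterministic.  Idempotent.
    """
    by_seq: dict[str, list[tuple[str, int]]] = {}
    for t in tiles:
        if isinstance(t, ConsolidatedTile):
            by_seq.setdefault(t.aa_seq, []).extend(t.sources)
        else:
            by_seq.setdefault(t.aa_seq, []).append((t.protein_id, t.start))
    return [
        ConsolidatedTile(aa, tuple(sorted(set(srcs))))
        for aa, srcs in sorted(by_seq.items())
    ]


def back_translate(aa_seq: str, rng_seed, forbidden_motifs=DEFAULT_FORBIDDEN_MOTIFS,
                   max_retries: int = 100) -> str:
    """Back-translate a peptide with uniformly sampled synonymous codons.

    Reproducible for a fixed seed.  If the assembled DNA (either strand)
    contains a forbidden motif, the codons overlapping the occurrence are
    resampled, up to ``max_retries`` times.
    """
    rng = as_rng(rng_seed)
    codons = []
    for aa in aa_seq:
        try:
            options = SYNONYMOUS_CODONS[aa]
        except KeyError:
            raise DesignError(f"cannot back-translate residue {aa!r}") from None
        codons.append(options[rng.integers(len(options))])

    def find_hit(dna: str):
        for motif in forbidden_motifs or ():
            for m in (motif, reverse_complement(motif)):
                i = dna.find(m)
                if i >= 0:
                    return i, i + len(m)
        return None

    for _ in range(max_retries):
        dna = "".join(codons)
        hit = find_hit(dna)
        if hit is None:
            return dna
        lo, hi = hit[0] // 3, (hit[1] + 2) // 3
        for j in range(lo, min(hi, len(codons))):
            options = SYNONYMOUS_CODONS[aa_seq[j]]
            codons[j] = options[rng.integers(len(options))]
    raise DesignError("could not avoid forbidden motifs after max_retries resamples")


def assemble_oligo(dna_seq: str, fwd_adapter: str = FWD_ADAPTER,
                   rev_adapter: str = REV_ADAPTER) -> str:
    if not dna_seq:
        raise DesignError("empty insert")
    return fwd_adapter + dna_seq + rev_adapter


def _kmer_coverage(proteins, tile_seqs, kmin=8, kmax=11) -> dict[int, float]:
    """Fraction of proteome k-mers contained in at least one tile."""
    cov = {}
    for k in range(kmin, kmax + 1):
        proteome_kmers = set()
        for p in proteins:
            s = p.sequence
            proteome_kmers.update(s[i:i + k] for i in range(len(s) - k + 1))
        tile_kmers = set()
        for s in tile_seqs:
            tile_kmers.update(s[i:i + k] for i in range(len(s) - k + 1))
        cov[k] = (len(proteome_kmers & tile_kmers) / len(proteome_kmers)
                  if proteome_kmers else 1.0)
    return cov


def read_proteome(fasta_path) -> list[ProteinRecord]:
    records = []
    for i, rec in enumerate(SeqIO.parse(str(fasta_path), "fasta")):
        seq = str(rec.seq).upper()
        if not seq:
            raise DesignError(f"record {i} ({rec.id!r}): empty sequence")
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise DesignError(f"no FASTA records in {fasta_path}")
    return records


def design_library(proteome, frag_len: int = 60, min_overlap: int = 30,
                   seed: int = 0, fwd_adapter: str = FWD_ADAPTER,
                   rev_adapter: str = REV_ADAPTER,
                   forbidden_motifs=DEFAULT_FORBIDDEN_MOTIFS):
    """Run the full design pipeline: tile -> consolidate -> back-translate -> flank.

    Parameters
    ----------
    proteome : path to a protein FASTA or a list of ProteinRecord.

    Returns
    -------
    (designs, report) : list of MinigeneDesign and a JSON-serializable report.
    """
    if isinstance(proteome, (str, Path)):
        proteins = read_proteome(proteome)
    else:
        proteins = [p if isinstance(p, ProteinRecord) else ProteinRecord(*p)
                    for p in proteome]

    tiles = []
    short_proteins = []
    for p in proteins:
        ts = tile_protein(p.sequence, frag_len, min_overlap, protein_id=p.protein_id)
        if len(p.sequence) < frag_len:
            short_proteins.append(p.protein_id)
        tiles.extend(ts)

    # tiles containing ambiguous residues cannot be back-translated; drop them
    clean, dropped_ambiguous = [], 0
    for t in tiles:
        if set(t.aa_seq) <= STANDARD_AA:
            clean.append(t)
        else:
            dropped_ambiguous += 1

    consolidated = consolidate_tiles(clean)
    rng = as_rng(seed)
    designs = []
    width = max(6, len(str(len(consolidated))))
    for i, ct in enumerate(consolidated):
        dna = back_translate(ct.aa_seq, rng, forbidden_motifs)
        designs.append(MinigeneDesign(
            minigene_id=f"MG{i:0{width}d}",
            aa_seq=ct.aa_seq,
            dna_seq=dna,
            oligo_seq=assemble_oligo(dna, fwd_adapter, rev_adapter),
            sources=ct.sources,
        ))

    report = {
        "n_proteins": len(proteins),
        "n_tiles": len(tiles),
        "n_tiles_dropped_ambiguous": dropped_ambiguous,
        "n_designs": len(designs),
        "short_proteins": sorted(short_proteins),
        "oligo_length_histogram": dict(sorted(
            Counter(len(d.oligo_seq) for d in designs).items())),
        "kmer_coverage": _kmer_coverage(proteins, [d.aa_seq for d in designs]),
        "frag_len": frag_len,
        "min_overlap": min_overlap,
        "seed": seed,
    }
    return designs, report


def write_design_outputs(designs, report, out_dir):
    """Write the design table (TSV), reference FASTA of inserts, and report JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = out / "designs.tsv"
    with open(tsv, "w") as fh:
        fh.write("# minigene_id\taa_seq\tdna_seq\toligo_seq\tsources "
                 "(protein_id:start;...)\n")
        fh.write("minigene_id\taa_seq\tdna_seq\toligo_seq\tsources\n")
        for d in designs:
            srcs = ";".join(f"{pid}:{start}" for pid, start in d.sources)
            fh.write(f"{d.minigene_id}\t{d.aa_seq}\t{d.dna_seq}\t{d.oligo_seq}\t{srcs}\n")
    fasta = out / "designs.fasta"
    with open(fasta, "w") as fh:
        for d in designs:
            fh.write(f">{d.minigene_id}\n{d.dna_seq}\n")
    with open(out / "design_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return tsv, fasta
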