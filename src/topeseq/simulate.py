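"""Synthetic screen generator.

Produces desk-scale inputs with the statistical structure the analysis
assumes: toy proteomes and genomes, library cell populations transduced at
Poisson MOI (so cells carry passenger minigenes alongside any true epitope),
FRET-gate sorting under a noisy-OR shift model with planted epitopes and an
endogenous background rate, sequencing reads or genomic insert records per
gate, and round-two (biopanning) libraries bottlenecked to round-one
Shifted-gate recoveries.

Default parameters follow the screening regime the analysis targets where
that regime is stated (MOI 7; probability thresholds at p < 0.01); the shift
probabilities themselves are synthetic choices picked for clear separation
between planted epitopes and passengers and are documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import as_rng, reverse_complement
from .design import FWD_ADAPTER, REV_ADAPTER, ProteinRecord
from .wes import FWD, REV, CodingSegment, InsertRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA"))

SHIFTED, UNSHIFTED = "Shifted", "Unshifted"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_proteins: int = 100
    protein_length_range: tuple = (80, 300)
    moi: float = 7.0  # mean integrated minigene copies per cell
    n_founder_cells: int = 500_000
    planted_epitopes: tuple = ()  # ((entity_id, shift_prob_true), ...)
    shift_prob_background: float = 0.002
    endogenous_background_rate: float = 0.05  # cell shifts regardless of cargo
    read_depth: int = 1_000_000  # reads per gate sample
    substitution_error_rate: float = 0.002
    spike_in: tuple | None = None  # (entity_id, n_cells)
    n_replicates: int = 2


@dataclass
class SimCells:
    """Cell population in flat-array form: cargo[offsets[i]:offsets[i+1]]
    are the design indices carried by cell i."""

    offsets: np.ndarray
    cargo: np.ndarray
    shifted: np.ndarray  # bool gate per cell
    design_ids: tuple[str, ...]

    @property
    def n_cells(self) -> int:
        return len(self.offsets) - 1


# ---------------------------------------------------------------------------
# Toy inputs


def make_toy_proteome(n_proteins: int, length_range=(80, 300), seed=0,
                      duplicated_region: int = 0) -> list[ProteinRecord]:
    """Random proteins over the 20-letter alphabet.

    ``duplicated_region``: length of a shared region copied verbatim into the
    first two proteins (at position 0) to exercise tile consolidation.
    """
    rng = as_rng(seed)
    lo, hi = length_range
    prots = []
    shared = "".join(AA[j] for j in rng.integers(0, 20, duplicated_region))
    for i in range(n_proteins):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(AA[j] for j in rng.integers(0, 20, L))
        if duplicated_region and i < 2:
            seq = shared + seq[duplicated_region:] if L > duplicated_region else shared
        prots.append(ProteinRecord(f"P{i:05d}", seq))
    return prots


def write_fasta(records, path):
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, ProteinRecord):
                fh.write(f">{rec.protein_id}\n{rec.sequence}\n")
            else:
                name, seq = rec
                fh.write(f">{name}\n{seq}\n")
    return Path(path)


def make_toy_genome(n_contigs: int = 1, segments_per_contig: int = 2,
                    codons_per_segment: int = 30, intergenic: int = 60,
                    seed=0):
    """Toy genome with stop-free CDS segments on alternating strands.

    Returns (genome dict, list of CodingSegment); annotated phase is 0.
    """
    rng = as_rng(seed)
    genome, segments = {}, []
    for ci in range(n_contigs):
        contig = f"chr{ci + 1}"
        parts, pos = [], 0

        def spacer():
            nonlocal pos
            s = "".join("ACGT"[j] for j in rng.integers(0, 4, intergenic))
            parts.append(s)
            pos += len(s)

        spacer()
        for si in range(segments_per_contig):
            coding = "".join(_NONSTOP_CODONS[j] for j in rng.integers(
                0, len(_NONSTOP_CODONS), codons_per_segment))
            strand = "+" if si % 2 == 0 else "-"
            embedded = coding if strand == "+" else reverse_complement(coding)
            segments.append(CodingSegment(contig, pos, pos + len(embedded), strand, 0))
            parts.append(embedded)
            pos += len(embedded)
            spacer()
        genome[contig] = "".join(parts)
    return genome, segments


#: toy MHC anchor preferences used by the synthetic binding predictor
_ANCHOR_P2, _ANCHOR_PC = "ST", "YF"


def toy_binding_rank(peptide: str) -> float:
    """Synthetic MHC-binding percentile rank (lower = better binder).

    A deterministic stand-in for an external binding predictor's rank-score
    table: peptides carrying both toy anchor residues (position 2 in
    {S, T}, C-terminus in {Y, F}) score rank 2, one anchor rank 10, none
    rank 50.  Used to build rank tables for the binding filter and to
    pre-filter the random-peptide baseline arm symmetrically.
    """
    rank = 50.0
    if len(peptide) >= 2 and peptide[1] in _ANCHOR_P2:
        rank /= 5.0
    if peptide and peptide[-1] in _ANCHOR_PC:
        rank /= 5.0
    return rank


def toy_rank_table(peptides, allele: str = "HLA-A*01:01") -> pd.DataFrame:
    """Rank-score table for a peptide list in predictor-export shape."""
    return pd.DataFrame({
        "peptide": list(peptides),
        "allele": allele,
        "rank": [toy_binding_rank(p) for p in peptides],
    })


# ---------------------------------------------------------------------------
# Cell population and gates


def _truncated_poisson(rng, mean: float, n: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1 (purity-sorted cells carry cargo)."""
    out = rng.poisson(mean, n)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(mean, int(zero.sum()))
        zero = out == 0
    return out


def simulate_cells(design_ids, config: SimConfig, rng=None,
                   cargo_probs=None) -> SimCells:
    """Simulate the transduced, purity-sorted, gate-assigned cell population.

    Each founder cell draws a cargo count ~ Poisson(MOI) conditioned >= 1 and
    cargo identities i.i.d. from ``cargo_probs`` (uniform by default).  The
    cell shifts with probability 1 - prod(1 - p_i) over its cargo (noisy-OR;
    p_i = the planted shift probability for planted entities, else the
    background), OR'd with the endogenous background rate.  Spike-in cells
    carry a single fixed cargo.
    """
    design_ids = tuple(design_ids)
    if not design_ids:
        raise SimulationError("no designs to simulate")
    rng = as_rng(config.seed if rng is None else rng)
    nd = len(design_ids)
    id_to_idx = {d: i for i, d in enumerate(design_ids)}

    p_design = np.full(nd, config.shift_prob_background)
    for entity, p_true in config.planted_epitopes:
        p_design[id_to_idx[entity]] = p_true

    n = config.n_founder_cells
    counts = _truncated_poisson(rng, config.moi, n)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    if cargo_probs is None:
        cargo = rng.integers(0, nd, offsets[-1])
    else:
        cargo_probs = np.asarray(cargo_probs, dtype=float)
        cargo = rng.choice(nd, size=offsets[-1], p=cargo_probs / cargo_probs.sum())

    with np.errstate(divide="ignore"):  # shift prob 1.0 -> log(0) -> certain
        log_keep = np.log1p(-p_design[cargo])
    cell_log = np.add.reduceat(log_keep, offsets[:-1])
    p_shift = 1.0 - np.exp(cell_log)
    p_shift = 1.0 - (1.0 - p_shift) * (1.0 - config.endogenous_background_rate)
    shifted = rng.random(n) < p_shift

    if config.spike_in is not None:
        entity, n_spike = config.spike_in
        idx = id_to_idx[entity]
        p = 1.0 - (1.0 - p_design[idx]) * (1.0 - config.endogenous_background_rate)
        offsets = np.concatenate([offsets, offsets[-1] + np.arange(1, n_spike + 1)])
        cargo = np.concatenate([cargo, np.full(n_spike, idx)])
        shifted = np.concatenate([shifted, rng.random(n_spike) < p])
    return SimCells(offsets, cargo, shifted, design_ids)


def sample_gate_reads(cells: SimCells, gate: str, depth: int, rng) -> np.ndarray:
    """Sample ``depth`` reads from a gate: uniform cell, then uniform cargo
    within the cell.  Returns the design index per read."""
    mask = cells.shifted if gate == SHIFTED else ~cells.shifted
    pool = np.flatnonzero(mask)
    if pool.size == 0:
        raise SimulationError(f"gate {gate} is empty")
    sizes = np.diff(cells.offsets)
    pick = pool[rng.integers(0, pool.size, depth)]
    within = rng.integers(0, sizes[pick])
    return cells.cargo[cells.offsets[pick] + within]


def simulate_wpc_counts(design_ids, config: SimConfig):
    """Simulate a complete WPC screen at the count level.

    One independent transduction and sort per replicate.  Returns
    (count table in GateCounts form, truth dict).
    """
    from .quant import build_count_table

    design_ids = tuple(design_ids)
    root = np.random.SeedSequence(config.seed)
    sample_counts = {}
    for rep_ss in root.spawn(config.n_replicates):
        rep = f"R{len(sample_counts) // 2 + 1}"
        rng = np.random.default_rng(rep_ss)
        cells = simulate_cells(design_ids, config, rng=rng)
        for gate in (SHIFTED, UNSHIFTED):
            reads = sample_gate_reads(cells, gate, config.read_depth, rng)
            bc = np.bincount(reads, minlength=len(design_ids))
            sample_counts[(rep, gate)] = {
                design_ids[i]: int(c) for i, c in enumerate(bc) if c > 0}
    truth = {
        "planted": {e: p for e, p in config.planted_epitopes},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
    }
    return build_count_table(sample_counts), truth


# ---------------------------------------------------------------------------
# Read-level output (WPC FASTQ)


def _mutate(seq: str, rng, err: float) -> str:
    if err <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < err)
    if hits.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in hits:
            choices = bases[bases != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_reads(entity_per_read, designs: dict, fastq1, fastq2, rng,
                   err: float = 0.002, read_len: int = 150,
                   fwd_adapter: str = FWD_ADAPTER, rev_adapter: str = REV_ADAPTER):
    """Write paired FASTQ for sampled reads.

    ``entity_per_read`` is an iterable of minigene ids; each read pair covers
    the amplicon fwd_adapter + insert + rev_adapter from both ends.  The
    sequencing primers anneal to the adapter regions, so each mate starts at
    the insert boundary and reads through into the opposite adapter when the
    insert is shorter than the read length.  Substitution errors at rate
    ``err``.
    """
    rng = as_rng(rng)
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for i, entity in enumerate(entity_per_read):
            amplicon = fwd_adapter + designs[entity] + rev_adapter
            r1 = _mutate(amplicon[len(fwd_adapter):][:read_len], rng, err)
            r2 = _mutate(reverse_complement(amplicon)[len(rev_adapter):][:read_len],
                         rng, err)
            q1, q2 = "I" * len(r1), "I" * len(r2)
            f1.write(f"@read{i} 1\n{r1}\n+\n{q1}\n")
            f2.write(f"@read{i} 2\n{r2}\n+\n{q2}\n")
    return Path(fastq1), Path(fastq2)


def simulate_wpc_fastq(designs: dict, config: SimConfig, out_dir):
    """Full read-level WPC simulation: cells -> gates -> paired FASTQ per
    (replicate, gate).  Returns ({(replicate, gate): (fq1, fq2)}, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = tuple(designs)
    root = np.random.SeedSequence(config.seed)
    files = {}
    for r, rep_ss in enumerate(root.spawn(config.n_replicates), start=1):
        rng = np.random.default_rng(rep_ss)
        cells = simulate_cells(ids, config, rng=rng)
        for gate in (SHIFTED, UNSHIFTED):
            reads = sample_gate_reads(cells, gate, config.read_depth, rng)
            names = [ids[j] for j in reads]
            fq1 = out / f"R{r}_{gate}_1.fastq"
            fq2 = out / f"R{r}_{gate}_2.fastq"
            simulate_reads(names, designs, fq1, fq2, rng,
                           err=config.substitution_error_rate)
            files[(f"R{r}", gate)] = (fq1, fq2)
    truth = {"planted": {e: p for e, p in config.planted_epitopes}}
    return files, truth


# ---------------------------------------------------------------------------
# WES mode: shotgun fragments over a toy genome


@dataclass(frozen=True)
class Fragment:
    contig: str
    a: int
    b: int
    orientation: str  # expressed strand

    def covers_in_frame(self, window, frame_offset: int = 0) -> bool:
        if self.contig != window.contig:
            return False
        if not (self.a <= window.w_start and window.w_end <= self.b):
            return False
        if window.strand == "+" and self.orientation == FWD:
            return (window.w_start - self.a) % 3 == frame_offset % 3
        if window.strand == "-" and self.orientation == REV:
            return (self.b - window.w_end) % 3 == frame_offset % 3
        return False


def make_fragment_pool(genome: dict, n_fragments: int, rng,
                       length_range=(150, 350)) -> list[Fragment]:
    """Random shotgun fragments: random contig (length-weighted), random
    breakpoints, random cloned orientation — the six-expression-state model."""
    rng = as_rng(rng)
    contigs = sorted(genome)
    lens = np.array([len(genome[c]) for c in contigs], dtype=float)
    frags = []
    for _ in range(n_fragments):
        ci = int(rng.choice(len(contigs), p=lens / lens.sum()))
        L = len(genome[contigs[ci]])
        flen = int(rng.integers(*length_range))
        flen = min(flen, L)
        a = int(rng.integers(0, L - flen + 1))
        frags.append(Fragment(contigs[ci], a, a + flen,
                              FWD if rng.random() < 0.5 else REV))
    return frags


def simulate_wes_inserts(genome: dict, planted_windows, config: SimConfig,
                         n_fragments: int = 5000, frame_offset: int = 0):
    """Simulate a WES screen: fragment pool -> cells -> per-gate inserts.

    ``planted_windows`` is a list of (PeptideWindow, shift_prob_true): any
    fragment covering a planted window in the congruent expression state
    triggers shifting at that probability.  Returns
    ({(replicate, gate): list[InsertRecord]}, fragment pool).
    """
    root = np.random.SeedSequence(config.seed)
    pool_rng = np.random.default_rng(root.spawn(1)[0])
    frags = make_fragment_pool(genome, n_fragments, pool_rng)

    p_frag = np.full(len(frags), config.shift_prob_background)
    for w, p_true in planted_windows:
        for i, f in enumerate(frags):
            if f.covers_in_frame(w, frame_offset):
                p_frag[i] = max(p_frag[i], p_true)
    frag_cfg = replace(config, planted_epitopes=tuple(
        (str(i), float(p_frag[i])) for i in range(len(frags))
        if p_frag[i] != config.shift_prob_background))

    samples = {}
    for r, rep_ss in enumerate(root.spawn(config.n_replicates + 1)[1:], start=1):
        rng = np.random.default_rng(rep_ss)
        cells = simulate_cells(tuple(str(i) for i in range(len(frags))),
                               frag_cfg, rng=rng)
        for gate in (SHIFTED, UNSHIFTED):
            idx = sample_gate_reads(cells, gate, config.read_depth, rng)
            samples[(f"R{r}", gate)] = [
                InsertRecord(frags[j].contig, frags[j].a, frags[j].b,
                             frags[j].orientation) for j in idx]
    return samples, frags


def inserts_to_sam(inserts, genome: dict, path, read_len: int = 75,
                   mapq: int = 60):
    """Write inserts as proper read pairs in a SAM file (for alignment-based
    pipelines): read 1 sits at the insert's expressed 5' end."""
    import pysam

    contigs = sorted(genome)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": len(genome[c])} for c in contigs]}
    tid = {c: i for i, c in enumerate(contigs)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, ins in enumerate(inserts):
            rl = min(read_len, ins.b - ins.a)
            left = pysam.AlignedSegment(out.header)
            right = pysam.AlignedSegment(out.header)
            for seg, start in ((left, ins.a), (right, ins.b - rl)):
                seg.query_name = f"frag{i}"
                seg.reference_id = tid[ins.contig]
                seg.reference_start = start
                seg.mapping_quality = mapq
                seg.cigarstring = f"{rl}M"
                seg.query_sequence = genome[ins.contig][start:start + rl]
                seg.query_qualities = pysam.qualitystring_to_array("I" * rl)
            left.is_reverse, right.is_reverse = False, True
            if ins.orientation == FWD:
                r1, r2 = left, right
            else:
                r1, r2 = right, left
            r1.is_read1, r2.is_read2 = True, True
            for seg, mate in ((r1, r2), (r2, r1)):
                seg.is_paired = True
                seg.is_proper_pair = True
                seg.next_reference_id = mate.reference_id
                seg.next_reference_start = mate.reference_start
                seg.mate_is_reverse = mate.is_reverse
                seg.template_length = (ins.b - ins.a) * (
                    1 if seg.reference_start == ins.a else -1)
            out.write(r1)
            out.write(r2)
    return Path(path)


# ---------------------------------------------------------------------------
# Biopanning


def simulate_panning(design_ids, config: SimConfig):
    """Two-round biopanning simulation at the count level.

    Round 1 runs under ``config``; the round-2 library's cargo frequencies
    are proportional to round 1's pooled Shifted-gate recoveries
    (bottlenecked diversity), and the screen is repeated.  Returns
    (round1 table, round2 table, truth).
    """
    from .quant import build_count_table

    design_ids = tuple(design_ids)
    r1_table, truth = simulate_wpc_counts(design_ids, config)

    shifted = r1_table[r1_table.gate == SHIFTED].groupby("entity_id")["raw_count"].sum()
    probs = np.zeros(len(design_ids))
    idx = {d: i for i, d in enumerate(design_ids)}
    for entity, c in shifted.items():
        probs[idx[entity]] = c
    if probs.sum() == 0:
        raise SimulationError("round-1 Shifted gate recovered nothing")

    cfg2 = replace(config, seed=config.seed + 1)
    root = np.random.SeedSequence(cfg2.seed)
    sample_counts = {}
    for r, rep_ss in enumerate(root.spawn(cfg2.n_replicates), start=1):
        rng = np.random.default_rng(rep_ss)
        cells = simulate_cells(design_ids, cfg2, rng=rng, cargo_probs=probs)
        for gate in (SHIFTED, UNSHIFTED):
            reads = sample_gate_reads(cells, gate, cfg2.read_depth, rng)
            bc = np.bincount(reads, minlength=len(design_ids))
            sample_counts[(f"R{r}", gate)] = {
                design_ids[i]: int(c) for i, c in enumerate(bc) if c > 0}
    r2_table = build_count_table(sample_counts)
    return r1_table, r2_table, truth
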