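# Methods

This note documents the models and procedures implemented in `topeseq`, the
parameters that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Library design (WPC)

A proteome is tiled into fragments of `frag_len` residues (default 60) at a
step of `frag_len − min_overlap` (default step 30), with a final tile
anchored at `max(0, L − frag_len)` so the C-terminus is always covered and
every pair of consecutive tiles overlaps by at least `min_overlap` residues.
With `min_overlap ≥ k − 1`, every k-mer peptide of the proteome (k = 8–11,
the class-I epitope length range) is contained in at least one tile; the
design report verifies this coverage. Proteins shorter than `frag_len`
produce one full-length tile and are flagged. Tiles containing ambiguous
residues (X/U/B/Z) are dropped — they cannot be back-translated — and
counted in the report.

Consolidation deduplicates tiles by exact amino-acid identity and merges
provenance, so identical domains shared by isoforms or paralogs enter the
library once. Inexact-homology clustering is deliberately out of scope.

Back-translation draws each codon uniformly from the synonymous set of the
standard genetic code, seeded for reproducibility. Uniform (non-native)
codon usage decorrelates the DNA of protein-overlapping tiles, which
prevents concatemerization of overlapping single-stranded oligos during
pooled PCR cloning. Assembled inserts are screened against the two
meganuclease recognition sites used in pooled cloning (I-SceI, PI-SceI;
configurable), on both strands; an occurrence triggers resampling of the
overlapping codons with a bounded retry count. For 18+ bp sites a collision
is vanishingly rare, so the retry bound is effectively never reached.

Adapter-annealing flanks (18 nt each) are added for amplification and
sequencing: a 60-residue tile yields 180 nt of coding sequence and a 216-nt
oligo.

## Read quantification (WPC)

Raw mates are 3′-adapter-trimmed (exact suffix/prefix matching against the
opposite amplification adapter) and kept iff ≥ 90% of bases exceed Q20
(`frac = 0.9`, `q = 20`; the fraction boundary is inclusive, the quality
comparison strict). Merging scans every overlap length in [20, 150] in both
innie and read-through ("outie") geometry, scores each candidate by
mismatch density in the overlap, and accepts the lowest-density (ties:
longest) candidate iff its density is ≤ 0.2 (inclusive). Disagreeing
overlap bases resolve to the higher-quality call (ties to mate 1).

Merged reads collapse by greedy sphere clustering: unique sequences visited
in descending abundance (ties lexicographic), each joining the most
abundant earlier centroid within Levenshtein distance 4, else founding a
centroid. Centroids are assigned to the unique nearest designed reference
within edit distance 3; equidistant nearest designs leave the read
unassigned ("ambiguous") rather than crediting one homologous tile
arbitrarily. The search uses a pigeonhole piece index (a read within
distance d shares at least one of d+1 contiguous reference pieces verbatim,
displaced by at most d), verified with banded edit distance; this is exact,
and the test suite checks equivalence against an exhaustive scan.
Normalization is reads-per-million within each (replicate, gate) sample;
any fixed scale cancels in rf_s. Unassigned and ambiguous reads are
reported but excluded from totals.

## Peptide-window counting (WES-style libraries)

Shotgun fragments are cloned without frame control, so a fragment expresses
its peptide in one of six states (two orientations × three codon offsets).
Entities are therefore genomic k-mer peptide loci, not fragments: for each
annotated CDS segment, every in-frame window of 3k bases inside the segment
is enumerated (k = 8–11), windows containing an in-frame stop are dropped,
and windows are deduplicated by locus. Exon-junction-spanning peptides are
out of scope, matching the format's known gap.

An insert counts toward a window iff it fully contains the window's span
("traversing": a partial fragment cannot encode the full peptide), matches
the window's strand, and is frame-congruent: for a forward insert and a +
window, `(w_start − a) mod 3 = frame_offset` (mirrored arithmetic on the
minus strand). The vector's frame offset is configurable (default 0; the
true offset depends on the cloning cassette). An optional open-frame mode
additionally requires the expressed frame to be stop-free from the insert's
5′ end to the window end, approximating ribosome plausibility; the default
counts purely by span and frame. Inserts derive from proper read pairs
passing mapping-quality (default ≥ 20) and duplicate filters; read 1's
strand defines the expressed orientation (adapter-side convention).
Identical peptides at distinct loci stay distinct by default, with a
peptide-collapsed aggregate view available.

Counting groups inserts by (contig, orientation, frame class) and evaluates
containment vectorized; a quadratic all-pairs oracle backs it in tests.

## Enrichment statistics

For each entity, `rf_s = S/(S+U)` over depth-normalized gate counts;
entities with zero counts in both gates of a replicate are dropped from
that replicate, and only entities scored in every replicate are combined
(geometric mean; a zero annihilates). Each combined score is standardized
against the mean and sample standard deviation (ddof = 1) of all scored
entities — the screen's own population serves as the null, since true hits
are assumed rare — giving a Z-score and a one-tailed upper p-value from the
standard normal; hits are p < alpha (default 0.01). A median/MAD
standardization and an additive pseudocount for sparse data are available
behind flags; no multiple-testing correction is applied by default
(screening threshold semantics), with Benjamini–Hochberg opt-in.

The normal approximation requires each entity's rf_s to be measured from
enough independent carrier cells; with few founder clones per entity the
score distribution is zero-inflated/bimodal and the tail calibration
degrades. The null-calibration test sizes its simulation accordingly
(~70 shifted carrier slots per entity).

## Motif refinement

Hits are decomposed into all embedded k-mers (k fixed per analysis, 8–11),
with provenance across *all* minigenes recorded. Peptides occurring in m ≥ 2
minigenes with s significant sources get an exact binomial upper-tail
p-value `P(X ≥ s)`, X ~ Binomial(m, q), where q is the observed library-wide
significant fraction (≈ alpha under the null); single-occurrence peptides
rest on their minigene's significance. The binding filter keeps peptides
with external-predictor percentile rank < 5 (strict), taking the best rank
across alleles; peptides absent from the table are removed and counted.

Clustering is a Gibbs sampler over assignments of same-length peptides to K
clusters. A cluster's model is its per-position amino-acid frequency matrix
with additive pseudocounts against a flat 1/20 background; a peptide's
score against a cluster is its summed positional log-odds in bits, always
computed leave-one-out (the peptide's own counts removed). Sampling runs a
geometric annealing schedule (T: 2.0 → 0.1 over 60 sweeps, best of 3
restarts); at zero temperature, trash moves activate: a peptide whose best
cluster score falls below the trash threshold (10 bits) parks in a trash
group and may rejoin once the models sharpen, iterated to a fixed point.
Per-cluster KLD is the mean leave-one-out member score; for a pure cluster
with zero pseudocounts this equals k·log2(20) bits exactly. K is selected
over a range (1–15 by default) by maximum mean per-cluster KLD.

Two choices depart from the reference clustering tool and matter:

* **Leave-one-out scoring.** Scoring a peptide against a model containing
  itself inflates small clusters; with the inter-cluster and shift penalties
  fixed at zero, that bias makes larger K always win. LOO removes it while
  preserving the closed form.
* **Pseudocount mass.** A per-cell pseudocount of 0.25 (total flat mass 5)
  is the flat approximation to BLOSUM-weighted pseudocounts. It penalizes
  fragmenting a coherent motif into small subclusters; with a mass-1
  pseudocount, splitting any cluster with residual entropy raises mean KLD
  and K-selection degenerates.

Cluster significance uses a baseline of KLD scores from clustering random
peptides matched in number and length, passed through the same binding
filter when one is in play — the filter matters: uniform random peptides
essentially never form 10-bit clusters, whereas rank-filtered peptides
share anchor positions and produce a proper chance-clique baseline. Ten
iterations of the full K-selection feed a normal fit (KS normality p
reported; parameters are estimated from the sample, so the KS p is
approximate in the Lilliefors sense); each experiment cluster gets a
one-sample Z and upper-tail p, significant at p < 0.01. Cluster membership
annotates hits and never filters them: a genuine epitope may fail to
cluster.

## Biopanning comparison

Two scored rounds are compared over their shared entities: incliners
(score rose), decliners (fell), and exact ties (reported separately; ties
are measure-zero on real data but must be handled). Rediscovery — round-1
hits significant again in round 2 — is reported against both natural
denominators (all round-1 hits, and those still present in round 2). Both
one-tailed exact binomial tests use the round-2 significant fraction among
round-2-present entities as the chance rate: the rediscovery test on
round-1 hits, and the incliner test on incliners that were null in round 1
and significant in round 2.

A model observation worth stating: with the noisy-OR gate model below, an
entity's expected rf_s is invariant to library composition (its Shifted and
Unshifted shares scale together), so panning does not raise rf_s in
expectation — the benefit of round 2 is statistical (bottlenecked diversity
concentrates reads and founder clones on survivors, tightening scores and
boosting significance). Accordingly the panning checks assert round-2
significance and library-frequency enrichment of planted epitopes plus both
binomial tests, and report the rf change rather than asserting its sign.
This matches the round-comparison picture in which bulk score changes split
roughly evenly between incliners and decliners.

## Synthetic screen generator

The generator produces the statistical structure the analysis assumes:

* **Cell library.** Each founder cell draws a cargo count ~ Poisson(MOI)
  conditioned ≥ 1 (purity-sorted), cargo identities i.i.d. from the library
  (weighted for round-2 libraries). MOI defaults to 7 — the high-MOI regime
  that maximizes library coverage at the price of passenger minigenes.
* **Gate model.** A cell shifts with probability
  `1 − Π(1 − p_i)` over its cargo (noisy-OR), OR'd with an endogenous
  background rate: planted epitopes have `shift_prob_true` (0.8 in the
  standard scenarios), everything else `shift_prob_background` (0.002), and
  `endogenous_background_rate` defaults to 0.05 — a few percent of target
  cells fall in the Shifted gate regardless of cargo, the chassis-derived
  background the assay design has to overcome. These probabilities are
  synthetic choices picked once for clear separation; nothing quantitative
  about shifting is derivable from first principles.
* **Reads.** Each read samples a uniform cell of its gate, then a uniform
  cargo element — so passengers of shifted cells contaminate the Shifted
  sample exactly as high-MOI transduction predicts. Default depth is 10⁶
  reads per gate and 5×10⁵ founder cells (~70 founder clones per minigene
  for a 5×10⁴-entity library) — desk-scale stand-ins for the much larger
  real campaigns. FASTQ output adds substitution errors (default 0.002).
  WES mode draws random fragments (breakpoint, length, orientation) over a
  toy genome and emits insert records or SAM proper pairs.
* **Panning.** Round-2 cargo frequencies are proportional to round-1
  Shifted-gate recoveries; the screen then reruns under the same gate
  model. Standard panning scenarios plant five epitopes: with a single
  true epitope the rediscovery binomial test is degenerate (one success at
  most).
* **Binding predictor.** `toy_binding_rank` is a deterministic synthetic
  stand-in for an MHC-binding predictor's rank table: position-2 {S,T} and
  C-terminal {Y,F} anchors map to rank 2, one anchor to 10, none to 50. It
  exists so the binding filter and the rank-filtered random baseline can be
  exercised without an external predictor.

What the generator does **not** emulate: fluorescence physics and sorting
impurity (a configurable sort-error rate exists but defaults to perfect
gates), amplification bias (optional log-normal factor only), indels and
quality-value structure in reads, homologous (inexact) proteome redundancy,
and exon structure beyond contiguous CDS segments. Passing tests therefore
demonstrate correctness of the analysis pipeline under the stated
statistical model, not robustness to every artifact of real screens.

## Problem sizes and determinism

The test and acceptance scenarios are sized for a laptop-class single CPU:
50,000-entity screens with 5×10⁵ founder cells and 10⁶ reads per gate at
the count level; ~200 designs × ~10³ reads for FASTQ-level checks;
200-peptide clustering runs with K ≤ 5 and 10 baseline iterations (the
calibration scenarios use 2 restarts × 40 sweeps; planted-motif recovery is
insensitive to this). All randomness flows from explicit seeds through
`numpy.random.Generator`; per-stage seeds derive from a run seed by hashing
the stage name, so stages are reproducible independently and identical
configurations yield byte-identical outputs.
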