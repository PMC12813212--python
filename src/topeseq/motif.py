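"""Motif-level refinement of screen hits.

Significant minigenes are decomposed into their embedded 8-11-mer peptides;
peptides recurring across multiple minigenes are tested for enrichment of
significant sources (exact binomial); peptides are optionally filtered on an
external MHC-binding percentile-rank table (low-stringency rank < 5); and
same-length peptide sets are clustered with a Gibbs sampler into positional
amino-acid motifs scored by Kullback-Leibler divergence (bits) against a
flat background.  Cluster significance is assessed against a baseline
distribution of KLD scores obtained by clustering random peptides of the
same number and length (one-sample Z-test on the normal fit).

Clustering annotates hits; it never filters them — an epitope that fails to
cluster remains a hit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import AA_ALPHABET, as_rng, encode_peptides

LOG2_20 = float(np.log2(20.0))


class MotifError(ValueError):
    pass


@dataclass
class PeptideHit:
    peptide: str
    sources: tuple  # of (minigene_id, z, is_hit)
    recurrence_p: float | None = None
    binding_rank: float | None = None

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_significant(self) -> int:
        return sum(1 for _, _, hit in self.sources if hit)


@dataclass
class MotifCluster:
    cluster_id: int
    members: tuple[str, ...]
    count_matrix: np.ndarray  # (20, k) per-position amino-acid counts
    kld: float  # mean per-member leave-one-out log-odds score, bits
    baseline_z: float | None = None
    baseline_p: float | None = None


@dataclass
class ClusterSolution:
    n_clusters: int
    clusters: list[MotifCluster]
    assignments: np.ndarray  # cluster index per input peptide, -1 = trash
    peptides: tuple[str, ...]

    @property
    def mean_kld(self) -> float:
        if not self.clusters:
            return 0.0
        return float(np.mean([c.kld for c in self.clusters]))


@dataclass
class BaselineDistribution:
    scores: np.ndarray
    mean: float
    sd: float
    ks_p: float


# ---------------------------------------------------------------------------
# k-mer extraction and filtering


def extract_kmers(minigenes: dict, significance, k: int) -> list[PeptideHit]:
    """All k-length peptides embedded in significant minigenes.

    ``minigenes`` maps minigene_id -> amino-acid sequence; ``significance``
    maps minigene_id -> (z, is_hit) or a DataFrame with entity_id/z/is_hit
    columns.  Provenance across ALL minigenes (hit or not) is recorded for
    the recurrence test.  Output deduplicated by peptide, lexicographic.
    """
    if isinstance(significance, pd.DataFrame):
        significance = {r.entity_id: (float(r.z), bool(r.is_hit))
                        for r in significance.itertuples()}
    index: dict[str, set] = {}
    for mid, seq in minigenes.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], set()).add(mid)
    out = []
    for pep in sorted(index):
        srcs = tuple(sorted(
            (mid, *significance.get(mid, (float("nan"), False)))
            for mid in index[pep]))
        if any(hit for _, _, hit in srcs):
            out.append(PeptideHit(pep, srcs))
    return out


def recurrence_test(m: int, s: int, q: float) -> float:
    """Upper-tail exact binomial p: P(X >= s), X ~ Binomial(m, q)."""
    if not 0 < q < 1:
        raise MotifError("background rate q must lie in (0, 1)")
    if not 0 <= s <= m:
        raise MotifError("need 0 <= s <= m")
    return float(stats.binom.sf(s - 1, m, q))


def annotate_recurrence(peptides: list[PeptideHit], q: float) -> list[PeptideHit]:
    """Attach the recurrence p-value to multi-source peptides.

    ``q`` is the library-wide fraction of significant minigenes.  Peptides
    occurring in a single minigene bypass the test (recurrence_p stays None).
    """
    for pep in peptides:
        if pep.n_sources >= 2:
            pep.recurrence_p = recurrence_test(pep.n_sources, pep.n_significant, q)
    return peptides


def binding_filter(peptides, rank_table, cutoff: float = 5.0):
    """Keep peptides with predictor percentile rank < cutoff (strict).

    ``rank_table`` is a DataFrame with peptide/allele/rank columns or a
    mapping peptide -> rank; with several alleles the best (minimum) rank is
    used.  Peptides absent from the table are removed.  Returns
    (kept peptides, report) where the report includes the fraction of hit
    minigenes retaining at least one passing peptide.
    """
    if isinstance(rank_table, pd.DataFrame):
        if len(rank_table) == 0:
            raise MotifError("empty binding-rank table")
        ranks = rank_table.groupby("peptide")["rank"].min().to_dict()
    else:
        ranks = dict(rank_table)
        if not ranks:
            raise MotifError("empty binding-rank table")

    kept, missing = [], 0
    for pep in peptides:
        seq = pep.peptide if isinstance(pep, PeptideHit) else pep
        r = ranks.get(seq)
        if r is None:
            missing += 1
            continue
        if r < cutoff:
            if isinstance(pep, PeptideHit):
                pep.binding_rank = float(r)
            kept.append(pep)

    def hit_mgs(pps):
        out = set()
        for p in pps:
            if isinstance(p, PeptideHit):
                out.update(mid for mid, _, hit in p.sources if hit)
        return out

    before, after = hit_mgs(peptides), hit_mgs(kept)
    report = {
        "n_input": len(list(peptides)),
        "n_kept": len(kept),
        "n_missing_from_table": missing,
        "hit_minigenes_with_passing_peptide": (
            len(after) / len(before) if before else float("nan")),
    }
    return kept, report


# ---------------------------------------------------------------------------
# Gibbs clustering


def _onehot(P: np.ndarray) -> np.ndarray:
    n, k = P.shape
    X = np.zeros((n, 20, k), dtype=np.float64)
    X[np.arange(n)[:, None], P, np.arange(k)[None, :]] = 1.0
    return X


def _loo_scores(P, X, C, sizes, assign, pseudocount):
    """Leave-one-out log-odds score (bits) of each peptide against each cluster.

    Returns an (n, K) array: the peptide's own counts are removed from the
    model of the cluster it is currently assigned to.
    """
    n, k = P.shape
    K = C.shape[0]
    pos = np.arange(k)
    # own-letter counts per cluster: (n, K, k)
    own = C[:, P, pos].transpose(1, 0, 2)
    eff_sizes = np.broadcast_to(sizes, (n, K)).copy()
    member = assign >= 0
    if member.any():
        idx = np.flatnonzero(member)
        own[idx, assign[idx], :] -= 1.0
        eff_sizes[idx, assign[idx]] -= 1.0
    denom = eff_sizes + 20.0 * pseudocount
    safe = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (own + pseudocount) / denom[:, :, None]
        contrib = np.log2(20.0 * f)
    scores = np.where(safe[:, :, None], contrib, 0.0).sum(axis=2)
    return scores


def gibbs_cluster(peptides, n_clusters: int, seed=0, trash_threshold: float = 10.0,
                  n_restarts: int = 3, n_sweeps: int = 60,
                  pseudocount: float = 0.25, t_start: float = 2.0,
                  t_end: float = 0.1) -> ClusterSolution:
    """Cluster same-length peptides into positional motifs by Gibbs sampling.

    Each cluster is a per-position amino-acid frequency model (pseudocount-
    smoothed, flat 1/20 background); a peptide's score against a cluster is
    its summed positional log-odds in bits, computed leave-one-out.  Sampling
    follows a simulated-annealing temperature schedule; the best of
    ``n_restarts`` (by mean per-cluster KLD after trash filtering) is kept.
    Peptides whose score against their final cluster falls below
    ``trash_threshold`` bits are moved to a trash group (assignment -1).
    Per-cluster KLD is the mean leave-one-out score of the retained members.
    """
    peptides = tuple(p.peptide if isinstance(p, PeptideHit) else p for p in peptides)
    n = len(peptides)
    if n < n_clusters:
        raise MotifError(f"{n} peptides cannot fill {n_clusters} clusters")
    P = encode_peptides(peptides)
    X = _onehot(P)
    k = P.shape[1]
    rng = as_rng(seed)
    temps = np.geomspace(t_start, t_end, n_sweeps)

    best: ClusterSolution | None = None
    for _restart in range(n_restarts):
        assign = rng.integers(0, n_clusters, n)
        C = np.stack([X[assign == c].sum(axis=0) for c in range(n_clusters)])
        sizes = np.bincount(assign, minlength=n_clusters).astype(float)

        def sweep(temperature: float | None, assign, C, sizes, trash: bool):
            """One pass over peptides; temperature None = deterministic argmax.
            With ``trash`` enabled a peptide whose best cluster score falls
            below the threshold parks in the trash group (and may rejoin in a
            later sweep once the models have sharpened)."""
            moved = 0
            for i in rng.permutation(n):
                c_old = assign[i]
                if c_old >= 0:
                    C[c_old] -= X[i]
                    sizes[c_old] -= 1
                    assign[i] = -1
                s = _loo_scores(P[i:i + 1], X[i:i + 1], C, sizes,
                                np.array([-1]), pseudocount)[0]
                if trash and s.max() < trash_threshold:
                    c_new = -1
                elif temperature is None:
                    c_new = int(np.argmax(s))
                else:
                    w = s / temperature
                    w = np.exp((w - w.max()) * np.log(2.0))
                    c_new = int(rng.choice(n_clusters, p=w / w.sum()))
                assign[i] = c_new
                if c_new >= 0:
                    C[c_new] += X[i]
                    sizes[c_new] += 1
                if c_new != c_old:
                    moved += 1
            return moved

        # annealing without trash moves lets motifs form; trash pruning is
        # then applied at zero temperature until a fixed point, allowing
        # peptides to rejoin a sharpened model
        for t in temps:
            sweep(t, assign, C, sizes, trash=False)
        for _ in range(30):
            if sweep(None, assign, C, sizes, trash=True) == 0:
                break

        clusters = []
        scores = _loo_scores(P, X, C, sizes, assign, pseudocount)
        for c in range(n_clusters):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            kld = float(scores[members, c].mean())
            clusters.append(MotifCluster(
                cluster_id=c,
                members=tuple(peptides[i] for i in members),
                count_matrix=C[c].copy(),
                kld=kld,
            ))
        sol = ClusterSolution(n_clusters, clusters, assign.copy(), peptides)
        if best is None or sol.mean_kld > best.mean_kld:
            best = sol
    # renumber clusters by descending KLD for stable reporting
    order = sorted(range(len(best.clusters)), key=lambda i: -best.clusters[i].kld)
    remap = {best.clusters[old].cluster_id: new for new, old in enumerate(order)}
    best.assignments = np.array([remap.get(a, -1) for a in best.assignments])
    best.clusters = [best.clusters[old] for old in order]
    for new, c in enumerate(best.clusters):
        c.cluster_id = new
    return best


def select_k(peptides, k_range=range(1, 16), seed=0, **gibbs_kw) -> ClusterSolution:
    """Run gibbs_cluster over a range of cluster numbers; keep the solution
    with the highest mean per-cluster KLD (ties: fewest clusters)."""
    peptides = list(peptides)
    best = None
    for K in k_range:
        if K > len(peptides):
            break
        sol = gibbs_cluster(peptides, K, seed=np.random.SeedSequence(
            [int(seed), K]).generate_state(1)[0], **gibbs_kw)
        if best is None or sol.mean_kld > best.mean_kld + 1e-12:
            best = sol
    if best is None:
        raise MotifError("no feasible cluster number in k_range")
    return best


def random_peptides(n: int, length: int, rng, rank_fn=None, cutoff: float = 5.0,
                    max_draws: int = 1000) -> list[str]:
    """Uniform i.i.d. peptides over the 20-letter alphabet, optionally
    pre-filtered with the same binding-rank cutoff as the experiment arm."""
    out: list[str] = []
    for _ in range(max_draws):
        if len(out) >= n:
            break
        batch = ["".join(AA_ALPHABET[j] for j in row)
                 for row in rng.integers(0, 20, size=(max(n - len(out), 16), length))]
        if rank_fn is not None:
            batch = [p for p in batch if rank_fn(p) < cutoff]
        out.extend(batch)
    if len(out) < n:
        raise MotifError("could not generate enough filtered random peptides")
    return out[:n]


def baseline_significance(solution: ClusterSolution, n_iterations: int = 10,
                          seed=0, k_range=range(1, 16), rank_fn=None,
                          cutoff: float = 5.0, alpha: float = 0.01,
                          **gibbs_kw):
    """Score experiment clusters against a random-peptide KLD baseline.

    For each iteration, random peptides matching the experiment's peptide
    count and length (and binding pre-filter, when a ``rank_fn`` is given)
    are clustered with select_k; all cluster KLDs of the top solution feed a
    normal fit (Kolmogorov-Smirnov normality p reported).  Each experiment
    cluster receives a one-sample Z and upper-tail p; significant iff
    p < ``alpha``.
    """
    n = len(solution.peptides)
    length = len(solution.peptides[0])
    rng = as_rng(seed)
    baseline_scores = []
    for it in range(n_iterations):
        peps = random_peptides(n, length, rng, rank_fn=rank_fn, cutoff=cutoff)
        sol = select_k(peps, k_range=k_range,
                       seed=np.random.SeedSequence([int(seed), 7919, it])
                       .generate_state(1)[0], **gibbs_kw)
        baseline_scores.extend(c.kld for c in sol.clusters)
    scores = np.asarray(baseline_scores, dtype=float)
    if scores.size < 2 or scores.std(ddof=1) == 0:
        raise MotifError("degenerate baseline distribution")
    mean, sd = float(scores.mean()), float(scores.std(ddof=1))
    ks_p = float(stats.kstest(scores, "norm", args=(mean, sd)).pvalue)
    baseline = BaselineDistribution(scores, mean, sd, ks_p)
    for c in solution.clusters:
        c.baseline_z = (c.kld - mean) / sd
        c.baseline_p = float(stats.norm.sf(c.baseline_z))
    return solution, baseline


def motif_matrix(cluster: MotifCluster, rf_scores=None):
    """Position count/frequency matrices and the ranked core alignment.

    Returns (counts, freqs, members): 20 x k DataFrames indexed by amino
    acid, and the member peptides ranked by their screen rf_s when
    ``rf_scores`` (peptide -> score) is given.
    """
    if not cluster.members:
        raise MotifError("empty cluster")
    k = len(cluster.members[0])
    counts = pd.DataFrame(cluster.count_matrix, index=list(AA_ALPHABET),
                          columns=range(1, k + 1))
    freqs = counts / counts.sum(axis=0)
    members = list(cluster.members)
    if rf_scores is not None:
        members.sort(key=lambda p: (-rf_scores.get(p, 0.0), p))
    return counts, freqs, members
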