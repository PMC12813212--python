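"""Shifted-gate enrichment statistics for sort-seq screens.

For each entity (designed minigene or peptide-window locus) the enrichment
statistic rf_s is the depth-normalized Shifted-gate count as a proportion of
the entity's total normalized count across both gates.  Replicates are
combined by geometric mean.  Because each rf_s is a sampling proportion of
the library population, the library-wide distribution of combined rf_s is
approximately normal; each entity gets a Z-score against the library mean/sd
and a one-tailed upper p-value, with hits called at p < alpha (default 0.01).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

SHIFTED, UNSHIFTED = "Shifted", "Unshifted"


class EnrichmentError(ValueError):
    pass


def rf_s(norm_shifted: float, norm_unshifted: float) -> float:
    """Shifted-gate relative frequency: s / (s + u)."""
    total = norm_shifted + norm_unshifted
    if total <= 0:
        raise EnrichmentError("rf_s undefined when both gate counts are zero")
    return norm_shifted / total

def combine_replicates(scores) -> float:
    """Geometric mean of per-replicate rf_s; any zero annihilates."""
    scores = list(scores)
    if not scores:
        raise EnrichmentError("no replicate scores to combine")
    if any(s < 0 or s > 1 for s in scores):
        raise EnrichmentError("rf_s scores must lie in [0, 1]")
    if any(s == 0 for s in scores):
        return 0.0
    return float(np.exp(np.mean(np.log(scores))))


def z_scores(combined_scores, alpha: float = 0.01, robust: bool = False):
    """Standardize scores against the library distribution.

    z = (score - mean) / sd with sample sd (ddof=1), or median/MAD
    standardization when ``robust``; p is the upper-tail standard-normal
    probability.  Returns (z, p) arrays.
    """
    x = np.asarray(list(combined_scores), dtype=float)
    if x.size < 3:
        raise EnrichmentError("need at least 3 entities to standardize")
    if robust:
        center = np.median(x)
        scale = stats.median_abs_deviation(x, scale="normal")
    else:
        center = x.mean()
        scale = x.std(ddof=1)
    if scale == 0:
        raise EnrichmentError("zero variance across entities")
    z = (x - center) / scale
    p = stats.norm.sf(z)
    return z, p


def score_screen(counts: pd.DataFrame, alpha: float = 0.01,
                 pseudocount: float = 0.0, robust: bool = False) -> pd.DataFrame:
    """Score a count table (entity_id, replicate, gate, norm_count).

    Entities with zero counts in both gates of a replicate are excluded from
    that replicate; only entities scored in every replicate are combined
    (complete-case).  Returns a ranked table with per-replicate rf_s, the
    geometric-mean combined score, z, one-tailed p, rank, percentile and hit
    flag at ``alpha``.
    """
    req = {"entity_id", "replicate", "gate", "norm_count"}
    if not req <= set(counts.columns):
        raise EnrichmentError(f"count table must have columns {sorted(req)}")
    wide = counts.pivot_table(index=["entity_id", "replicate"], columns="gate",
                              values="norm_count", aggfunc="sum", fill_value=0.0)
    for gate in (SHIFTED, UNSHIFTED):
        if gate not in wide.columns:
            wide[gate] = 0.0
    wide = wide + pseudocount
    tot = wide[SHIFTED] + wide[UNSHIFTED]
    wide = wide[tot > 0]
    scores = (wide[SHIFTED] / (wide[SHIFTED] + wide[UNSHIFTED])).unstack("replicate")
    replicates = list(scores.columns)
    scores = scores.dropna()  # complete-case across replicates
    if scores.empty:
        raise EnrichmentError("no entity scored in all replicates")
    combined = scores.apply(lambda row: combine_replicates(row.values), axis=1)
    z, p = z_scores(combined.values, alpha=alpha, robust=robust)
    out = pd.DataFrame({"entity_id": combined.index, "rf_s_combined": combined.values,
                        "z": z, "p": p})
    for r in replicates:
        out[f"rf_s_{r}"] = scores[r].values
    out["is_hit"] = out["p"] < alpha
    out = out.sort_values(["rf_s_combined", "entity_id"],
                          ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    out["percentile"] = 100.0 * (1.0 - out["rank"] / len(out))
    return out.reset_index(drop=True)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (opt-in column)."""
    return stats.false_discovery_control(np.asarray(p), method="bh")


def screen_report(records: pd.DataFrame, controls=None):
    """Summarize a scored screen and annotate named control entities."""
    summary = {
        "n_entities": int(len(records)),
        "n_hits": int(records["is_hit"].sum()),
        "hit_fraction": float(records["is_hit"].mean()),
        "controls": {},
    }
    for cid in controls or ():
        row = records[records["entity_id"] == cid]
        if row.empty:
            summary["controls"][cid] = {"status": "not detected"}
        else:
            r = row.iloc[0]
            summary["controls"][cid] = {
                "status": "detected",
                "rank": int(r["rank"]),
                "percentile": float(r["percentile"]),
                "rf_s_combined": float(r["rf_s_combined"]),
                "z": float(r["z"]),
                "p": float(r["p"]),
                "is_hit": bool(r["is_hit"]),
            }
    return summary


def write_enrichment(records: pd.DataFrame, summary: dict, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "enrichment.tsv", "w") as fh:
        fh.write("# entity_id, per-replicate rf_s, geometric-mean rf_s, "
                 "library Z-score, one-tailed p, rank, percentile, hit flag\n")
        records.to_csv(fh, sep="\t", index=False)
    with open(out / "enrichment_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return out / "enrichment.tsv"
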