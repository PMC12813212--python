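"""Round-comparison statistics for iterative biopanning screens.

A second screening round re-expresses the material recovered from the first
round's Shifted gate, bottlenecking library diversity and (for true
epitopes) increasing enrichment.  Comparing the two rounds over the entities
present in both yields the summary metrics: incliner/decliner fractions,
the rediscovery rate of first-round hits, the incliner share of second-round
hits, and the fraction of incliners newly significant in round two — with
one-tailed exact binomial tests against chance rediscovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class PanningError(ValueError):
    pass


def _binom_upper(s: int, n: int, rate: float) -> float:
    """One-tailed exact binomial p: P(X >= s), X ~ Binomial(n, rate)."""
    if not 0 < rate < 1:
        raise PanningError("null rate must lie in (0, 1)")
    if s > n or s < 0:
        raise PanningError("need 0 <= s <= n")
    return float(stats.binom.sf(s - 1, n, rate))


def rediscovery_test(s_redisc: int, n_sig1_present: int, null_rate: float) -> float:
    """P that >= s_redisc of n first-round hits recur by chance at null_rate."""
    return _binom_upper(s_redisc, n_sig1_present, null_rate)


def incliner_enrichment_test(n_new_sig_incliners: int, n_incliners: int,
                             null_rate: float) -> float:
    """P that >= s of n incliners become newly significant by chance."""
    return _binom_upper(n_new_sig_incliners, n_incliners, null_rate)


@dataclass
class RoundComparison:
    per_entity: pd.DataFrame  # entity_id, score_r1, score_r2, sig_r1, sig_r2, trend
    summary: dict
    test_ps: dict


def compare_rounds(r1: pd.DataFrame, r2: pd.DataFrame,
                   alpha: float = 0.01) -> RoundComparison:
    """Compare two scored rounds (enrichment tables with entity_id,
    rf_s_combined, p columns) over their shared entities.

    Exact score ties count as neither incliner nor decliner and are reported
    separately.  Rediscovery is computed with both natural denominators: all
    round-1 hits, and round-1 hits still present in round 2.  Null rates for
    both binomial tests are the round-2 significant fraction among entities
    present in round 2.
    """
    for name, df in (("round 1", r1), ("round 2", r2)):
        if not {"entity_id", "rf_s_combined", "p"} <= set(df.columns):
            raise PanningError(f"{name} table lacks entity_id/rf_s_combined/p")
    a = r1.set_index("entity_id")[["rf_s_combined", "p"]]
    b = r2.set_index("entity_id")[["rf_s_combined", "p"]]
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise PanningError("no entities shared between rounds")
    m = pd.DataFrame({
        "entity_id": shared,
        "score_r1": a.loc[shared, "rf_s_combined"].values,
        "score_r2": b.loc[shared, "rf_s_combined"].values,
        "sig_r1": (a.loc[shared, "p"] < alpha).values,
        "sig_r2": (b.loc[shared, "p"] < alpha).values,
    })
    m["trend"] = np.select(
        [m.score_r2 > m.score_r1, m.score_r2 < m.score_r1],
        ["incliner", "decliner"], default="tie")

    n_both = len(m)
    n_inc = int((m.trend == "incliner").sum())
    n_dec = int((m.trend == "decliner").sum())
    n_tie = n_both - n_inc - n_dec
    sig1_all = int((r1["p"] < alpha).sum())
    sig1_present = int(m.sig_r1.sum())
    redisc = int((m.sig_r1 & m.sig_r2).sum())
    sig2_present = int(m.sig_r2.sum())
    null_rate = sig2_present / n_both
    inc_sig2 = int(((m.trend == "incliner") & m.sig_r2).sum())
    new_sig_inc = int(((m.trend == "incliner") & ~m.sig_r1 & m.sig_r2).sum())

    summary = {
        "alpha": alpha,
        "n_round1": int(len(r1)),
        "n_round2": int(len(r2)),
        "n_shared": n_both,
        "n_dropped_in_round2": int(len(r1) - n_both),
        "pct_incliners": 100.0 * n_inc / n_both,
        "pct_decliners": 100.0 * n_dec / n_both,
        "pct_ties": 100.0 * n_tie / n_both,
        "n_sig_round1": sig1_all,
        "n_sig_round1_present_round2": sig1_present,
        "n_sig_round2_present": sig2_present,
        "n_rediscovered": redisc,
        "pct_sig_r1_rediscovered_of_all": (
            100.0 * redisc / sig1_all if sig1_all else float("nan")),
        "pct_sig_r1_rediscovered_of_present": (
            100.0 * redisc / sig1_present if sig1_present else float("nan")),
        "pct_incliners_of_sig_r2": (
            100.0 * inc_sig2 / sig2_present if sig2_present else float("nan")),
        "pct_incliners_newly_sig": (
            100.0 * new_sig_inc / n_inc if n_inc else float("nan")),
    }
    test_ps = {}
    if sig1_present and 0 < null_rate < 1:
        test_ps["rediscovery_p"] = rediscovery_test(redisc, sig1_present, null_rate)
    if n_inc and 0 < null_rate < 1:
        test_ps["incliner_enrichment_p"] = incliner_enrichment_test(
            new_sig_inc, n_inc, null_rate)
    return RoundComparison(m.reset_index(drop=True), summary, test_ps)
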