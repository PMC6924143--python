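"""Position-free motif enrichment and motif-effect statistics.

Two complementary analyses of labelled, activity-scored ODN sets:

* occurrence-difference ranking — for every motif of length 2..6, the
  percentage of ODNs containing it in the high- and low-activity groups and
  the absolute difference, ranked descending (the top of this table names
  the motifs that most distinguish active from inactive ODNs);
* Mann–Whitney motif effects — within one activity group, compare the
  activity scores of ODNs containing a motif against those without it
  (two-sided Mann–Whitney U; exact null when the smaller subset has ≤ 8
  members and there are no ties, otherwise the normal approximation with
  tie and continuity corrections), flagging significance at p < 0.05 and a
  direction from the median comparison.

Motif containment here is position-free, unlike the positional fingerprint
dictionary used for classification features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import OdnRecord

INCREASE = "increase"
DECREASE = "decrease"
NONE = "none"


def _all_motifs(records: Sequence[OdnRecord], min_len: int, max_len: int) -> set[str]:
    out: set[str] = set()
    for rec in records:
        seq = rec.sequence
        for k in range(min_len, max_len + 1):
            for i in range(len(seq) - k + 1):
                out.add(seq[i : i + k])
    return out


def _containment_fraction(records: Sequence[OdnRecord], motif: str) -> float:
    return sum(motif in r.sequence for r in records) / len(records)


def group_occurrence_diff(
    high: Sequence[OdnRecord],
    low: Sequence[OdnRecord],
    min_len: int = 2,
    max_len: int = 6,
) -> pd.DataFrame:
    """Per-motif containment percentages in each group and their absolute
    difference, ranked descending (ties: lexicographic motif order).

    Columns: motif, pct_high, pct_low, abs_diff — all in percentage points.
    """
    if not high or not low:
        raise ValueError("group_occurrence_diff: both groups must be non-empty")
    motifs = sorted(_all_motifs(list(high) + list(low), min_len, max_len))
    rows = []
    for m in motifs:
        ph = 100.0 * _containment_fraction(high, m)
        pl = 100.0 * _containment_fraction(low, m)
        rows.append((m, ph, pl, abs(ph - pl)))
    df = pd.DataFrame(rows, columns=["motif", "pct_high", "pct_low", "abs_diff"])
    return df.sort_values(
        ["abs_diff", "motif"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class MotifEffect:
    """Effect of one motif's presence on activity scores within a group."""

    motif: str
    n_with: int
    n_without: int
    median_with: float | None
    median_without: float | None
    p_value: float | None
    direction: str  # increase / decrease / none
    significant: bool
    method: str  # 'exact', 'asymptotic' or 'undefined'


def mann_whitney_effect(
    records: Sequence[OdnRecord],
    motif: str,
    alpha: float = 0.05,
    exact_max_n: int = 8,
) -> MotifEffect:
    """Two-sided Mann–Whitney U test of activity with vs without ``motif``.

    Every record must carry an activity score. If either subset is empty
    the effect is flagged undefined (p None, direction 'none').
    """
    with_scores = [r.activity for r in records if motif in r.sequence]
    without_scores = [r.activity for r in records if motif not in r.sequence]
    if any(s is None for s in with_scores + without_scores):
        raise ValueError("all records need activity scores")
    n_with, n_without = len(with_scores), len(without_scores)
    if n_with == 0 or n_without == 0:
        return MotifEffect(
            motif=motif, n_with=n_with, n_without=n_without,
            median_with=float(np.median(with_scores)) if with_scores else None,
            median_without=float(np.median(without_scores)) if without_scores else None,
            p_value=None, direction=NONE, significant=False, method="undefined",
        )
    pooled = with_scores + without_scores
    has_ties = len(set(pooled)) < len(pooled)
    if min(n_with, n_without) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        with_scores, without_scores, alternative="two-sided",
        method=method, use_continuity=True,
    )
    med_w = float(np.median(with_scores))
    med_wo = float(np.median(without_scores))
    if med_w > med_wo:
        direction = INCREASE
    elif med_w < med_wo:
        direction = DECREASE
    else:
        direction = NONE
    p = float(min(res.pvalue, 1.0))
    return MotifEffect(
        motif=motif, n_with=n_with, n_without=n_without,
        median_with=med_w, median_without=med_wo,
        p_value=p, direction=direction, significant=p < alpha, method=method,
    )


def motif_effect_table(
    records: Sequence[OdnRecord],
    motifs: Sequence[str] | None = None,
    alpha: float = 0.05,
    min_len: int = 2,
    max_len: int = 6,
    add_bh: bool = False,
) -> pd.DataFrame:
    """Mann–Whitney effect rows for each motif (alphabetical order).

    With ``add_bh=True`` a Benjamini–Hochberg adjusted-p column is appended;
    the raw per-motif p values remain the primary output.
    """
    if motifs is None:
        motifs = sorted(_all_motifs(records, min_len, max_len))
    rows = [mann_whitney_effect(records, m, alpha=alpha) for m in motifs]
    df = pd.DataFrame(
        {
            "motif": [r.motif for r in rows],
            "n_with": [r.n_with for r in rows],
            "n_without": [r.n_without for r in rows],
            "median_with": [r.median_with for r in rows],
            "median_without": [r.median_without for r in rows],
            "direction": [r.direction for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
            "method": [r.method for r in rows],
        }
    )
    if add_bh:
        mask = df["p_value"].notna()
        adj = pd.Series(np.nan, index=df.index)
        if mask.any():
            adj[mask] = stats.false_discovery_control(df.loc[mask, "p_value"], method="bh")
        df["p_bh"] = adj
    return df
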