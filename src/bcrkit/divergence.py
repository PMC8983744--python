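"""Germinal-centre divergence analysis between two samples.

For each V-(D-)J clone lineage present with enough reads in both samples,
the per-read %diversity from the germline V segment (100 x mismatches /
aligned V span) is compared between the samples with Welch's two-sample
t test.  At a P-value cutoff (default 0.01) lineages fall into four
groups:

* group 1 — significantly more diverged in sample 1,
* group 2 — more diverged in sample 1, not significant,
* group 3 — significantly less diverged in sample 1,
* group 4 — less diverged in sample 1, not significant,

and the overall odds score is (|g1|/|g2|) / (|g3|/|g4|): a ratio of
ratios summarising whether SHM accumulated differentially across the
whole lineage set.  Lineages where either sample has fewer than
``min_copies`` reads (default 100) are excluded — diversity resolution is
insufficient below that.  Exact mean ties count as "not more diverged in
sample 1" (groups 3/4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .clonal import lineage_key


def percent_diversity(table: pd.DataFrame) -> pd.Series:
    """Per-read %diversity vs the germline V: 100 x mismatches / span.

    Computed over the aligned V span only (the junction is excluded).
    """
    span = (table["bk_v_gend"] - table["bk_v_gstart"]).astype(float)
    return 100.0 * table["bk_v_mut_count"].astype(float) / span


def filter_lineages(
    counts1: pd.Series, counts2: pd.Series, min_copies: int = 100
) -> list[str]:
    """Lineage keys with at least ``min_copies`` reads in both samples."""
    shared = counts1.index.intersection(counts2.index)
    kept = [k for k in shared if counts1[k] >= min_copies and counts2[k] >= min_copies]
    return sorted(kept)


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t test (unequal variances), two-sided.

    Returns (t, df, p) with t = (mean(x)-mean(y)) / sqrt(s1^2/n1 + s2^2/n2)
    and Welch-Satterthwaite degrees of freedom.  Both samples need at
    least two observations; if both variances are zero the statistic is 0
    with p = 1 for equal means, +/-inf with p = 0 otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_test requires at least 2 observations per sample")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float(np.sign(diff) * np.inf), float(n1 + n2 - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return float(t), float(df), p


@dataclass
class DivergenceResult:
    """Per-lineage Welch statistics, four-group labels and the odds score."""

    per_lineage: pd.DataFrame
    group_counts: dict[int, int]
    odds_score: float
    p_cutoff: float
    continuity_corrected: bool
    min_copies: int = 100
    excluded: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "odds_score": self.odds_score,
            "log_odds": float(np.log(self.odds_score)),
            "n_lineages_tested": int(len(self.per_lineage)),
            "group_counts": {str(k): v for k, v in sorted(self.group_counts.items())},
            "p_cutoff": self.p_cutoff,
            "min_copies": self.min_copies,
            "continuity_corrected": self.continuity_corrected,
        }


def classify_and_odds(per_lineage: pd.DataFrame, p_cutoff: float = 0.01) -> DivergenceResult:
    """Assign the four-group labels and compute the odds score.

    ``per_lineage`` needs columns mean1, mean2 and p.  Zero cells in the
    2x2 group table are handled with the Haldane-Anscombe +0.5 continuity
    correction, flagged in the result.
    """
    df = per_lineage.copy()
    more = df["mean1"] > df["mean2"]
    sig = df["p"] < p_cutoff
    group = np.where(more, np.where(sig, 1, 2), np.where(sig, 3, 4))
    df["group"] = group
    counts = {g: int((group == g).sum()) for g in (1, 2, 3, 4)}
    cells = np.array([counts[1], counts[2], counts[3], counts[4]], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    odds = (cells[0] / cells[1]) / (cells[2] / cells[3])
    return DivergenceResult(
        per_lineage=df,
        group_counts=counts,
        odds_score=float(odds),
        p_cutoff=p_cutoff,
        continuity_corrected=corrected,
    )


def divergence_analysis(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    min_copies: int = 100,
    p_cutoff: float = 0.01,
    level: str = "gene",
) -> DivergenceResult:
    """Full two-sample divergence analysis from rearrangement tables.

    Sample 1 is conventionally the immunized/stimulated sample.  Returns
    per-lineage Welch statistics, group labels, and the odds score.
    """
    k1 = lineage_key(table1, level)
    k2 = lineage_key(table2, level)
    d1 = percent_diversity(table1)
    d2 = percent_diversity(table2)
    counts1 = k1.value_counts()
    counts2 = k2.value_counts()
    kept = filter_lineages(counts1, counts2, min_copies)
    excluded = sorted(set(counts1.index).intersection(counts2.index) - set(kept))
    if not kept:
        empty = pd.DataFrame(
            columns=["lineage_key", "n1", "n2", "mean1", "mean2", "t", "df", "p", "group"]
        )
        result = classify_and_odds(empty.assign(mean1=[], mean2=[], p=[]), p_cutoff)
        result.per_lineage = empty
        result.min_copies = min_copies
        result.excluded = excluded
        return result

    rows = []
    for key in kept:
        x = d1[k1 == key].values
        y = d2[k2 == key].values
        t, dof, p = welch_test(x, y)
        rows.append(
            {
                "lineage_key": key,
                "n1": int(x.size),
                "n2": int(y.size),
                "mean1": float(x.mean()),
                "mean2": float(y.mean()),
                "t": t,
                "df": dof,
                "p": p,
            }
        )
    result = classify_and_odds(pd.DataFrame(rows), p_cutoff)
    result.min_copies = min_copies
    result.excluded = excluded
    return result
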