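"""Repertoire-level descriptive statistics.

Segment usage frequencies, V(D)J combination link tables (with a
Circos-format text export), CDR3 length and amino-acid composition,
junctional N/P addition distributions, productive fraction,
Shannon-Weaver diversity and rarefaction.

The Shannon-Weaver index is

    H' = - sum_i (n_i / N) ln(n_i / N)

over the abundances n_i of the S distinct species (clonotypes by
default), N = sum n_i, natural logarithm.  A greater H' reflects greater
sample diversity; H' = 0 for a single species and H' = ln S for S
equally abundant species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


# -- segment name grouping -------------------------------------------------

def segment_group(call: str, level: str) -> str:
    """Collapse a segment call to ``allele``, ``gene`` or ``subfamily`` level."""
    if level == "allele":
        return call
    gene = call.split("*", 1)[0]
    if level == "gene":
        return gene
    if level == "subfamily":
        return re.split(r"[-/]", gene, maxsplit=1)[0]
    raise ValueError(f"unknown grouping level {level!r}")


# -- usage -----------------------------------------------------------------

def usage_frequencies(
    table: pd.DataFrame,
    segment_type: str,
    weight_by_duplicates: bool = True,
    productive_only: bool = False,
    level: str = "allele",
) -> pd.DataFrame:
    """Percentage frequency use of V, D or J segments.

    Returns a table of (segment_id, read_count, percent_frequency),
    percent over all annotated reads in scope (non-productive included by
    default).  For D, reads with an unassigned D are excluded from the
    denominator and reported in the table attribute ``n_unassigned``.
    """
    if segment_type not in ("V", "D", "J"):
        raise ValueError("segment_type must be V, D or J")
    if table.empty:
        raise ValueError("empty rearrangement table")
    df = table[table["productive"]] if productive_only else table
    col = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment_type]
    weights = df["duplicate_count"] if weight_by_duplicates else pd.Series(1, index=df.index)
    calls = df[col].fillna("")
    assigned = calls != ""
    n_unassigned = int(weights[~assigned].sum())
    grouped = (
        pd.DataFrame({"segment_id": calls[assigned].map(lambda c: segment_group(c, level)),
                      "w": weights[assigned]})
        .groupby("segment_id")["w"]
        .sum()
        .sort_index()
    )
    total = grouped.sum()
    out = pd.DataFrame(
        {
            "segment_id": grouped.index,
            "read_count": grouped.values.astype(int),
            "percent_frequency": 100.0 * grouped.values / total,
        }
    ).reset_index(drop=True)
    out.attrs["n_unassigned"] = n_unassigned
    out.attrs["segment_type"] = segment_type
    return out


# -- V(D)J combination links ----------------------------------------------

def vdj_links(table: pd.DataFrame, level: str = "subfamily") -> pd.DataFrame:
    """Counts and relative frequencies of V-(D-)J combinations.

    Rows with an unassigned D keep an empty d_group so that V-J pairing
    is still represented.  Frequencies sum to 1.
    """
    if table.empty:
        raise ValueError("empty rearrangement table")
    df = pd.DataFrame(
        {
            "v_group": table["v_call"].map(lambda c: segment_group(c, level)),
            "d_group": table["d_call"].fillna("").map(
                lambda c: segment_group(c, level) if c else ""
            ),
            "j_group": table["j_call"].map(lambda c: segment_group(c, level)),
            "w": table["duplicate_count"],
        }
    )
    links = (
        df.groupby(["v_group", "d_group", "j_group"])["w"]
        .sum()
        .reset_index()
        .rename(columns={"w": "count"})
        .sort_values(["v_group", "d_group", "j_group"], kind="stable")
        .reset_index(drop=True)
    )
    links["relative_frequency"] = links["count"] / links["count"].sum()
    return links


def circos_export(links: pd.DataFrame, karyotype_path: str | Path, links_path: str | Path) -> None:
    """Write Circos-format karyotype and link text files.

    Each segment group becomes an ideogram whose size equals its total
    link count (so ideogram space is proportional to observation
    frequency); every V-(D-)J combination becomes one link line joining
    consecutive coordinate windows on the V and J ideograms, with the D
    group and count carried in the options field.
    """
    totals: dict[str, int] = {}
    for _, row in links.iterrows():
        for col in ("v_group", "j_group"):
            totals[row[col]] = totals.get(row[col], 0) + int(row["count"])
    with open(karyotype_path, "w") as fh:
        for i, (name, size) in enumerate(sorted(totals.items())):
            fh.write(f"chr - {name} {name} 0 {size} chr{i % 24 + 1}\n")
    cursor = {name: 0 for name in totals}
    with open(links_path, "w") as fh:
        for _, row in links.iterrows():
            c = int(row["count"])
            v, j = row["v_group"], row["j_group"]
            v0, j0 = cursor[v], cursor[j]
            cursor[v] += c
            cursor[j] += c
            d = row["d_group"] if row["d_group"] else "."
            fh.write(f"{v} {v0} {v0 + c} {j} {j0} {j0 + c} d={d},count={c}\n")


def circos_import(links_path: str | Path) -> pd.DataFrame:
    """Re-read a links file written by :func:`circos_export`."""
    rows = []
    with open(links_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 7:
                continue
            opts = dict(kv.split("=") for kv in parts[6].split(","))
            d = opts.get("d", ".")
            rows.append(
                {
                    "v_group": parts[0],
                    "d_group": "" if d == "." else d,
                    "j_group": parts[3],
                    "count": int(opts["count"]),
                }
            )
    out = pd.DataFrame(rows, columns=["v_group", "d_group", "j_group", "count"])
    if not out.empty:
        out["relative_frequency"] = out["count"] / out["count"].sum()
    return out


# -- CDR3 statistics -------------------------------------------------------

def cdr3_length_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Histogram of CDR3 amino-acid lengths over productive reads.

    Returns (length, count) rows; the duplicate-weighted mean length (2
    decimals) is stored in ``attrs["mean_length"]``.
    """
    df = table[(table["productive"]) & (table["cdr3_aa"].fillna("") != "")]
    if df.empty:
        raise ValueError("no productive reads with a CDR3")
    lengths = df["cdr3_aa"].str.len()
    weights = df["duplicate_count"]
    hist = (
        pd.DataFrame({"length": lengths, "w": weights})
        .groupby("length")["w"]
        .sum()
        .rename("count")
        .reset_index()
    )
    mean = float(np.average(lengths, weights=weights))
    hist.attrs["mean_length"] = round(mean, 2)
    return hist


def aa_composition(table: pd.DataFrame) -> pd.Series:
    """Amino-acid frequencies over concatenated productive CDR3s (sums to 1)."""
    df = table[(table["productive"]) & (table["cdr3_aa"].fillna("") != "")]
    if df.empty:
        raise ValueError("no productive reads with a CDR3")
    counts: dict[str, int] = {}
    for aa_seq, w in zip(df["cdr3_aa"], df["duplicate_count"]):
        for aa in aa_seq:
            counts[aa] = counts.get(aa, 0) + int(w)
    total = sum(counts.values())
    return pd.Series({aa: c / total for aa, c in sorted(counts.items())}, name="frequency")


# -- junctional additions --------------------------------------------------

def np_addition_distribution(table: pd.DataFrame) -> dict[str, pd.Series]:
    """Histograms of junctional N and P lengths, with means in ``attrs``.

    Keys: ``n1``, ``n2`` (IGH only), ``p`` (pooled P lengths over all
    ends) and ``np1``/``np2`` (pooled P+N per junction, for comparisons
    that do not separate the two).
    """
    if table.empty:
        raise ValueError("empty rearrangement table")
    out: dict[str, pd.Series] = {}

    def hist(series: pd.Series, name: str) -> pd.Series:
        h = series.value_counts().sort_index()
        h.name = name
        h.attrs["mean"] = float(series.mean())
        return h

    out["n1"] = hist(table["bk_n1"].fillna("").str.len(), "n1")
    out["np1"] = hist(table["np1_length"], "np1")
    if (table["d_call"].fillna("") != "").any():
        out["n2"] = hist(table["bk_n2"].fillna("").str.len(), "n2")
        out["np2"] = hist(table["np2_length"], "np2")
    p_lengths = pd.concat(
        [table[c].fillna("").str.len() for c in ("bk_p_v", "bk_p_d5", "bk_p_d3", "bk_p_j")],
        ignore_index=True,
    )
    out["p"] = hist(p_lengths, "p")
    return out


# -- diversity -------------------------------------------------------------

@dataclass
class DiversityResult:
    """Shannon-Weaver diversity of a sample.

    ``h_prime`` in nats; ``n_total`` total reads (N); ``n_species``
    distinct species (S); ``counts`` the per-species abundances n_i.
    """

    h_prime: float
    n_total: int
    n_species: int
    counts: np.ndarray

    @property
    def h_max(self) -> float:
        return float(np.log(self.n_species))

    @property
    def evenness(self) -> float:
        return self.h_prime / self.h_max if self.n_species > 1 else 1.0


def shannon_index(counts) -> DiversityResult:
    """Shannon-Weaver H' = -sum (n_i/N) ln(n_i/N) over positive counts."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if (counts <= 0).any():
        raise ValueError("all counts must be positive (drop zeros first)")
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return DiversityResult(
        h_prime=max(h, 0.0),
        n_total=int(counts.sum()),
        n_species=int(counts.size),
        counts=counts.astype(int),
    )


def clonotype_key(table: pd.DataFrame) -> pd.Series:
    """Joined CDR1+CDR2+CDR3 amino-acid key per read."""
    return (
        table["cdr1_aa"].fillna("")
        + "|"
        + table["cdr2_aa"].fillna("")
        + "|"
        + table["cdr3_aa"].fillna("")
    )


def sample_diversity(table: pd.DataFrame, unit: str = "clonotype") -> DiversityResult:
    """Shannon-Weaver diversity of a rearrangement table.

    ``unit`` selects the species definition: ``"clonotype"`` (joined
    CDR1-2-3 sequence, the default) or ``"read"`` (unique annotated read
    sequence).  Abundances are duplicate-weighted.
    """
    if unit == "clonotype":
        keys = clonotype_key(table)
    elif unit == "read":
        keys = table["sequence"]
    else:
        raise ValueError(f"unknown diversity unit {unit!r}")
    counts = (
        pd.DataFrame({"k": keys, "w": table["duplicate_count"]}).groupby("k")["w"].sum()
    )
    return shannon_index(counts.values)


def rarefaction_curve(
    table: pd.DataFrame,
    depths,
    replicates: int = 20,
    rng: np.random.Generator | None = None,
    unit: str = "clonotype",
) -> pd.DataFrame:
    """Mean distinct-species count in uniform subsamples without replacement.

    Reads are expanded by duplicate_count before subsampling.  Returns
    (depth, mean_species) rows; the curve is monotone non-decreasing in
    depth and bounded by the total species count S.
    """
    rng = rng or np.random.default_rng(0)
    keys = clonotype_key(table) if unit == "clonotype" else table["sequence"]
    pool = np.repeat(keys.values, table["duplicate_count"].values.astype(int))
    codes = pd.factorize(pool)[0]
    n = codes.size
    rows = []
    for depth in depths:
        if depth > n:
            raise ValueError(f"depth {depth} exceeds total reads {n}")
        means = [
            np.unique(rng.choice(codes, size=int(depth), replace=False)).size
            for _ in range(replicates)
        ]
        rows.append({"depth": int(depth), "mean_species": float(np.mean(means))})
    return pd.DataFrame(rows)


def productive_fraction(table: pd.DataFrame) -> float:
    """Percent of annotated reads that are productive (duplicate-weighted)."""
    if table.empty:
        raise ValueError("empty rearrangement table")
    w = table["duplicate_count"]
    return float(100.0 * w[table["productive"]].sum() / w.sum())
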