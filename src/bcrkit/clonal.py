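"""Clonotype and clone-lineage analysis.

Reads are grouped two ways: a *clonotype* is a unique joined CDR1-CDR2-
CDR3 amino-acid sequence; a *clone lineage* is the set of reads sharing a
V-(D-)J segment typing (the operational surrogate for "descended from one
rearrangement event").  Lineages are ranked by copy number and named
CLH001, CLH002, ... (heavy) / CLL001, ... (kappa).

SHM position profiling: the mutation rate at a germline position is the
percentage of lineage reads carrying a point mutation there (10 reads, 3
mutated at one position -> 30%).  Because variable-region lengths differ
between lineages, positions are rescaled onto a common 1..100 index using
the lineage's mean variable-region length, which makes profiles
comparable across lineages (one index unit is roughly one amino acid).

Dendrograms: neighbour-joining trees over pairwise normalised edit
distances between clonotype amino-acid sequences, with leaf copy-number
overlays capped at 50 reads.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .annotate import mutations_from_str
from .germline import GermlineDatabase, v_region_label
from .stats import clonotype_key, segment_group

DENDROGRAM_COPY_CAP = 50


# -- grouping --------------------------------------------------------------

def group_clonotypes(table: pd.DataFrame) -> pd.DataFrame:
    """One row per distinct CDR1-2-3 joined sequence.

    Copy counts are conserved: the summed clonotype copies equal the
    summed read duplicate counts.
    """
    for col in ("cdr1_aa", "cdr2_aa", "cdr3_aa"):
        if col not in table.columns:
            raise ValueError(f"missing column {col}")
    df = table.assign(_key=clonotype_key(table))
    grouped = df.groupby("_key", sort=False).agg(
        copy_count=("duplicate_count", "sum"),
        n_reads=("sequence_id", "size"),
        read_ids=("sequence_id", lambda s: ";".join(s)),
    )
    grouped = grouped.sort_values(
        ["copy_count", "_key"], ascending=[False, True], kind="stable"
    ).reset_index().rename(columns={"_key": "clonotype_key"})
    return grouped


def lineage_key(table: pd.DataFrame, level: str = "gene", with_cdr3_length: bool = False) -> pd.Series:
    """V-(D-)J typing key per read, at allele or gene grouping level.

    ``with_cdr3_length`` appends the CDR3 length to the key — a stricter
    lineage definition for repertoires where one V-D-J combination hosts
    many independent rearrangements.
    """
    key = (
        table["v_call"].map(lambda c: segment_group(c, level))
        + "|"
        + table["d_call"].fillna("").map(lambda c: segment_group(c, level) if c else "")
        + "|"
        + table["j_call"].map(lambda c: segment_group(c, level))
    )
    if with_cdr3_length:
        key = key + "|" + table["cdr3_aa"].fillna("").str.len().astype(str)
    return key


def group_lineages(
    table: pd.DataFrame,
    level: str = "gene",
    with_cdr3_length: bool = False,
) -> pd.DataFrame:
    """Partition reads into clone lineages and assign rank names.

    Names are CLH### (IGH) or CLL### (IGK) in descending copy-count
    order, ties broken by key order.  Every annotated read belongs to
    exactly one lineage.
    """
    if table.empty:
        raise ValueError("empty rearrangement table")
    locus = table["locus"].iloc[0]
    prefix = "CLH" if locus == "IGH" else "CLL"
    df = table.assign(_key=lineage_key(table, level, with_cdr3_length))
    grouped = df.groupby("_key").agg(
        copy_count=("duplicate_count", "sum"),
        n_reads=("sequence_id", "size"),
        v_call=("v_call", "first"),
        d_call=("d_call", "first"),
        j_call=("j_call", "first"),
        mean_length=("sequence", lambda s: float(np.mean([len(x) for x in s]))),
        read_ids=("sequence_id", lambda s: ";".join(s)),
    )
    grouped = grouped.sort_values(
        ["copy_count", "_key"], ascending=[False, True], kind="stable"
    ).reset_index().rename(columns={"_key": "lineage_key"})
    grouped.insert(0, "name", [f"{prefix}{i + 1:03d}" for i in range(len(grouped))])
    return grouped


def top_lineages(lineages: pd.DataFrame, n: int) -> pd.DataFrame:
    """The n largest lineages (the whole table if it has fewer)."""
    return lineages.head(n).copy()


def lineage_members(table: pd.DataFrame, lineage_row) -> pd.DataFrame:
    ids = set(lineage_row["read_ids"].split(";"))
    return table[table["sequence_id"].isin(ids)]


# -- immunization fold change ---------------------------------------------

def lineage_fold_change(
    lineages_pre: pd.DataFrame,
    lineages_post: pd.DataFrame,
    per_reads: int = 10_000,
    pre_total: int | None = None,
    post_total: int | None = None,
) -> pd.DataFrame:
    """Per-lineage fold change of normalised copy numbers, post vs pre.

    Copies are normalised to ``per_reads`` sequencing depth in each
    sample; the depths default to each table's total copies but can be
    given explicitly when the tables are filtered subsets of a sample.
    A lineage absent pre-immunization receives a pseudocount of one
    normalised copy and is flagged (``pre_pseudocount``), never silently
    divided by zero.
    """
    pre_total = pre_total if pre_total is not None else lineages_pre["copy_count"].sum()
    post_total = post_total if post_total is not None else lineages_post["copy_count"].sum()
    pre_norm = dict(
        zip(lineages_pre["lineage_key"], lineages_pre["copy_count"] * per_reads / pre_total)
    )
    rows = []
    for _, row in lineages_post.iterrows():
        post_n = row["copy_count"] * per_reads / post_total
        pre_n = pre_norm.get(row["lineage_key"])
        pseudo = pre_n is None
        rows.append(
            {
                "lineage_key": row["lineage_key"],
                "name": row.get("name", ""),
                "pre_copies_norm": 1.0 if pseudo else float(pre_n),
                "post_copies_norm": float(post_n),
                "fold_change": float(post_n / (1.0 if pseudo else pre_n)),
                "pre_pseudocount": pseudo,
            }
        )
    return pd.DataFrame(rows)


# -- SHM position profiling ------------------------------------------------

@dataclass
class MutationProfile:
    """Per-position SHM rates on the 1..100 normalised index."""

    index: np.ndarray  # 1..100
    rate: np.ndarray  # percent, one per index
    region: list[str]  # FR/CDR label per index
    mean_length: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": self.index, "rate": self.rate, "region": self.region})


def shm_position_profile(members: pd.DataFrame, db: GermlineDatabase) -> pd.DataFrame:
    """Raw per-germline-position mutation rates for one clone lineage.

    Rate at position p = 100 x (reads mutated at p) / (reads whose V
    alignment covers p).  Positions are 0-based coordinates on the
    lineage's germline V; all covered positions are reported, mutated or
    not, with their FR/CDR region label.
    """
    if members.empty:
        raise ValueError("lineage has no member reads")
    v_calls = members["v_call"].unique()
    v = db[v_calls[0]]
    gstarts = members["bk_v_gstart"].values.astype(int)
    gends = members["bk_v_gend"].values.astype(int)
    max_pos = int(gends.max())
    min_pos = int(gstarts.min())
    coverage = np.zeros(max_pos, dtype=int)
    for g0, g1 in zip(gstarts, gends):
        coverage[g0:g1] += 1
    mutated = np.zeros(max_pos, dtype=int)
    for muts in members["bk_v_mutations"]:
        for pos, _a, _b in mutations_from_str(muts):
            if pos < max_pos:
                mutated[pos] += 1
    positions = np.arange(min_pos, max_pos)
    covered = coverage[min_pos:max_pos] > 0
    rate = np.zeros(positions.size)
    rate[covered] = 100.0 * mutated[min_pos:max_pos][covered] / coverage[min_pos:max_pos][covered]
    return pd.DataFrame(
        {
            "position": positions[covered],
            "rate": rate[covered],
            "n_covering": coverage[min_pos:max_pos][covered],
            "n_mutated": mutated[min_pos:max_pos][covered],
            "region": [v_region_label(v, int(p)) for p in positions[covered]],
        }
    )


def normalize_profile(raw: pd.DataFrame, mean_length: float) -> MutationProfile:
    """Rescale a raw profile onto the 1..100 length-normalised index.

    Position p (0-based) maps to index round(100 * (p + 1) / mean_length)
    clipped to [1, 100]; rates falling in the same index bin are
    averaged; bins receiving no position stay at rate 0 and inherit the
    nearest preceding region label.
    """
    if mean_length <= 0:
        raise ValueError("mean_length must be positive")
    idx = np.clip(
        np.round(100.0 * (raw["position"].values + 1) / mean_length).astype(int), 1, 100
    )
    rate = np.zeros(100)
    region = ["FR1"] * 100
    frame = pd.DataFrame({"i": idx, "rate": raw["rate"].values, "region": raw["region"].values})
    by_bin = frame.groupby("i")
    for i, sub in by_bin:
        rate[i - 1] = sub["rate"].mean()
        region[i - 1] = sub["region"].mode().iloc[0]
    # forward-fill labels through empty bins (e.g. beyond the V end)
    last = region[0]
    filled = set(by_bin.groups)
    for k in range(100):
        if (k + 1) in filled:
            last = region[k]
        else:
            region[k] = last
    return MutationProfile(
        index=np.arange(1, 101), rate=rate, region=region, mean_length=float(mean_length)
    )


def lineage_profile(
    members: pd.DataFrame, db: GermlineDatabase, mean_length: float | None = None
) -> MutationProfile:
    """Raw profile + normalisation in one step.

    ``mean_length`` defaults to the mean variable-region (read) length of
    the lineage members.
    """
    raw = shm_position_profile(members, db)
    if mean_length is None:
        mean_length = float(members["sequence"].str.len().mean())
    return normalize_profile(raw, mean_length)


def aggregate_profiles(profiles: list[MutationProfile], weights=None) -> pd.DataFrame:
    """Mean profile across lineages (unweighted by default, optionally
    weighted by lineage copy numbers)."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    mat = np.vstack([p.rate for p in profiles])
    if weights is None:
        mean = mat.mean(axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        mean = (mat * w[:, None]).sum(axis=0) / w.sum()
    return pd.DataFrame({"index": np.arange(1, 101), "rate": mean})


def shm_burden(members: pd.DataFrame, min_mutations: int = 2) -> float:
    """Percent of lineage reads with at least ``min_mutations`` variable-
    region mutations (duplicate-weighted)."""
    if members.empty:
        raise ValueError("lineage has no member reads")
    w = members["duplicate_count"].values.astype(float)
    hit = members["bk_v_mut_count"].values >= min_mutations
    return float(100.0 * w[hit].sum() / w.sum())


# -- dendrograms -----------------------------------------------------------

@dataclass
class ClonalTree:
    newick: str
    overlay: pd.DataFrame  # leaf_id, copy_count, overlay, capped
    distance_matrix: pd.DataFrame


def nj_newick(distances: np.ndarray, ids: list[str]) -> str:
    """Neighbour-joining tree (Newick) from a square distance matrix.

    On an additive matrix NJ recovers the generating topology and branch
    lengths exactly.  One and two taxa are handled as degenerate trees.
    """
    distances = np.asarray(distances, dtype=float)
    n = len(ids)
    if distances.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if n == 1:
        return f"{ids[0]}:0;"
    if n == 2:
        half = distances[0, 1] / 2.0
        return f"({ids[0]}:{half:.6f},{ids[1]}:{half:.6f});"
    from skbio import DistanceMatrix
    from skbio.tree import nj as _skbio_nj

    tree = _skbio_nj(DistanceMatrix(distances, ids))
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def normalized_edit_distance(a: str, b: str) -> float:
    """Levenshtein distance divided by the longer sequence length."""
    if not a and not b:
        return 0.0
    d = edlib.align(a, b)["editDistance"]
    return d / max(len(a), len(b))


def nj_tree(
    sequences: list[str],
    ids: list[str] | None = None,
    copy_counts: list[int] | None = None,
    copy_cap: int = DENDROGRAM_COPY_CAP,
) -> ClonalTree:
    """Neighbour-joining tree over normalised edit distances.

    Leaf overlays carry min(copy_count, cap) with a flag when the cap
    bites — dendrogram leaves are shown with a maximum of 50 reads.
    Degenerate cases: one sequence gives a single-leaf tree, two give a
    single edge split evenly.
    """
    n = len(sequences)
    if n == 0:
        raise ValueError("no sequences")
    ids = ids or [f"S{i + 1}" for i in range(n)]
    copy_counts = copy_counts if copy_counts is not None else [1] * n
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = normalized_edit_distance(sequences[i], sequences[j])
    dmat = pd.DataFrame(dm, index=ids, columns=ids)

    newick = nj_newick(dm, ids)

    overlay = pd.DataFrame(
        {
            "leaf_id": ids,
            "copy_count": copy_counts,
            "overlay": [min(int(c), copy_cap) for c in copy_counts],
            "capped": [int(c) > copy_cap for c in copy_counts],
        }
    )
    return ClonalTree(newick=newick, overlay=overlay, distance_matrix=dmat)


def lineage_dendrogram(
    members: pd.DataFrame, max_clonotypes: int | None = None, copy_cap: int = DENDROGRAM_COPY_CAP
) -> ClonalTree:
    """NJ dendrogram of the clonotypes within one clone lineage, built on
    CDR3 amino-acid sequences and overlaid with clonotype copy numbers."""
    clones = group_clonotypes(members)
    cdr3 = members.assign(_key=clonotype_key(members)).groupby("_key")["cdr3_aa"].first()
    if max_clonotypes is not None:
        clones = clones.head(max_clonotypes)
    seqs = [cdr3[k] if isinstance(cdr3[k], str) else "" for k in clones["clonotype_key"]]
    labels = [f"CT{i + 1:03d}" for i in range(len(clones))]
    return nj_tree(seqs, labels, clones["copy_count"].tolist(), copy_cap)
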