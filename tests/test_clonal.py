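"""Clonal grouping, SHM profiles, fold change and NJ dendrograms."""

import io as _io
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bcrkit
from bcrkit import clonal
from conftest import mk_table


# -- clonotypes -------------------------------------------------------------

def test_identical_cdr123_merge_into_one_clonotype():
    t = mk_table([
        {"cdr3_aa": "CARDY", "sequence": "AAA"},
        {"cdr3_aa": "CARDY", "sequence": "AAT"},  # differs outside CDRs
        {"cdr3_aa": "CARDF", "sequence": "AAA"},
    ])
    clones = clonal.group_clonotypes(t)
    assert len(clones) == 2
    assert clones["copy_count"].iloc[0] == 2


def test_clonotype_copy_conservation(clonal_igh):
    _, res = clonal_igh
    clones = clonal.group_clonotypes(res.table)
    assert clones["copy_count"].sum() == res.table["duplicate_count"].sum()


# -- lineages ---------------------------------------------------------------

def test_lineage_grouping_and_naming():
    t = mk_table([
        {"v_call": "V1*01", "d_call": "D1*01", "j_call": "J1*01"},
        {"v_call": "V1*01", "d_call": "D1*01", "j_call": "J1*01"},
        {"v_call": "V2*01", "d_call": "D1*01", "j_call": "J1*01"},
    ])
    lin = clonal.group_lineages(t)
    assert len(lin) == 2
    assert lin["name"].tolist() == ["CLH001", "CLH002"]
    assert lin["copy_count"].tolist() == [2, 1]


def test_allele_vs_gene_level_grouping():
    t = mk_table([
        {"v_call": "V1*01"}, {"v_call": "V1*02"},
    ])
    assert len(clonal.group_lineages(t, level="gene")) == 1
    assert len(clonal.group_lineages(t, level="allele")) == 2


def test_kappa_lineages_use_cll_prefix():
    t = mk_table([{"locus": "IGK", "d_call": ""}])
    assert clonal.group_lineages(t)["name"].iloc[0] == "CLL001"


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.tuples(st.sampled_from("ABC"), st.sampled_from("XY")), min_size=1, max_size=25))
def test_lineage_partition_property(pairs):
    """Every read lands in exactly one lineage; copies are conserved."""
    t = mk_table([
        {"v_call": f"V{a}*01", "j_call": f"J{b}*01", "duplicate_count": i + 1}
        for i, (a, b) in enumerate(pairs)
    ])
    lin = clonal.group_lineages(t)
    members = [rid for ids in lin["read_ids"] for rid in ids.split(";")]
    assert sorted(members) == sorted(t["sequence_id"])
    assert lin["copy_count"].sum() == t["duplicate_count"].sum()


def test_top_lineages_selection_and_ties():
    t = mk_table([
        {"v_call": "V1*01"}, {"v_call": "V1*01"},
        {"v_call": "V2*01"}, {"v_call": "V3*01"},
    ])
    lin = clonal.group_lineages(t)
    top2 = clonal.top_lineages(lin, 2)
    assert top2["copy_count"].tolist() == [2, 1]
    assert top2["lineage_key"].iloc[1] < lin["lineage_key"].iloc[2]  # tie by key order
    assert len(clonal.top_lineages(lin, 10)) == 3


# -- fold change ------------------------------------------------------------

def test_fold_change_equal_depths():
    pre = pd.DataFrame({"lineage_key": ["L1"], "copy_count": [10]})
    post = pd.DataFrame({"lineage_key": ["L1"], "copy_count": [100]})
    out = clonal.lineage_fold_change(pre, post, pre_total=5000, post_total=5000)
    assert out["fold_change"].iloc[0] == pytest.approx(10.0)
    equal = clonal.lineage_fold_change(pre, pre, pre_total=5000, post_total=5000)
    assert equal["fold_change"].iloc[0] == pytest.approx(1.0)


def test_fold_change_depth_normalization():
    pre = pd.DataFrame({"lineage_key": ["L1", "Lz"], "copy_count": [5, 4995]})
    post = pd.DataFrame({"lineage_key": ["L1", "Lz"], "copy_count": [20, 9980]})
    out = clonal.lineage_fold_change(pre, post)
    l1 = out.set_index("lineage_key").loc["L1"]
    # (20/10k per 10k) / (5/5k per 10k) = 2.0
    assert l1["fold_change"] == pytest.approx(2.0)


def test_fold_change_pseudocount_flagged():
    pre = pd.DataFrame({"lineage_key": ["L1"], "copy_count": [10_000]})
    post = pd.DataFrame({"lineage_key": ["L1", "L2"], "copy_count": [5000, 5000]})
    out = clonal.lineage_fold_change(pre, post).set_index("lineage_key")
    assert bool(out.loc["L2", "pre_pseudocount"])
    assert out.loc["L2", "fold_change"] == pytest.approx(5000.0)
    assert not bool(out.loc["L1", "pre_pseudocount"])


# -- SHM profile ------------------------------------------------------------

def _lineage_table(n_reads, mutated, position, v_call="IGHV1-10*01", span=290):
    rows = []
    for i in range(n_reads):
        mut = i < mutated
        rows.append({
            "v_call": v_call,
            "sequence": "A" * (span + 60),
            "bk_v_gstart": 0,
            "bk_v_gend": span,
            "bk_v_mutations": f"{position}:A>G" if mut else "",
            "bk_v_mut_count": 1 if mut else 0,
        })
    return mk_table(rows)


def test_worked_example_three_of_ten_is_30_percent(db):
    """10 reads in a lineage, 3 mutated at one position -> rate 30%."""
    t = _lineage_table(10, 3, 150)
    raw = clonal.shm_position_profile(t, db)
    assert raw.set_index("position").loc[150, "rate"] == 30.0
    assert (raw.loc[raw["position"] != 150, "rate"] == 0.0).all()


def test_unmutated_lineage_gives_zero_profile(db):
    t = _lineage_table(8, 0, 0)
    raw = clonal.shm_position_profile(t, db)
    assert (raw["rate"] == 0.0).all()


def test_denominator_counts_covering_reads_only(db):
    t = _lineage_table(10, 2, 280)
    # four reads end before position 280: not covering, excluded there
    t.loc[6:, "bk_v_gend"] = 270
    raw = clonal.shm_position_profile(t, db).set_index("position")
    assert raw.loc[280, "n_covering"] == 6
    assert raw.loc[280, "rate"] == pytest.approx(100.0 * 2 / 6)


def test_normalized_profile_has_no_gaps():
    """Reads of length 99 and 101 (mean 100) fill all 100 index bins."""
    raw = pd.DataFrame({
        "position": np.arange(0, 101),
        "rate": np.zeros(101),
        "region": ["FR1"] * 101,
    })
    raw.loc[50, "rate"] = 40.0
    profile = clonal.normalize_profile(raw, mean_length=100.0)
    assert profile.index.tolist() == list(range(1, 101))
    assert profile.rate[50] == 40.0  # index 51 -> bin 51
    assert len(profile.rate) == 100
    assert (profile.rate >= 0).all() and (profile.rate <= 100).all()


def test_profile_region_labels(db, clonal_igh):
    _, res = clonal_igh
    lin = clonal.group_lineages(res.table)
    members = clonal.lineage_members(res.table, lin.iloc[0])
    profile = clonal.lineage_profile(members, db)
    labels = set(profile.region)
    assert {"FR1", "CDR1", "FR2", "CDR2", "FR3"} <= labels


def test_shm_burden_examples():
    t = mk_table([
        {"bk_v_mut_count": 0}, {"bk_v_mut_count": 1}, {"bk_v_mut_count": 2},
        {"bk_v_mut_count": 5}, {"bk_v_mut_count": 0},
    ])
    assert clonal.shm_burden(t) == pytest.approx(40.0)
    assert clonal.shm_burden(t.iloc[:2]) == 0.0


def test_shm_burden_matches_binomial_tail(db):
    """Simulated lineage burden ~ binomial tail P(X >= 2) within 3 SE."""
    rate, length = 0.01, None
    cfg = bcrkit.SimulationConfig(
        n_reads=600, n_lineages=1, shm_rate=rate, hotspot_multiplier=1.0,
        seed=91, identifiable=False,
        expansion_dist={"kind": "fixed", "value": 600},
    )
    rep = bcrkit.simulate_repertoire(db, cfg)
    table = bcrkit.truth_to_rearrangement(rep.records, db, "IGH")
    v_len = table["bk_v_gend"].iloc[0]
    from scipy.stats import binom

    p_tail = 1.0 - binom.cdf(1, v_len, rate)
    observed = clonal.shm_burden(table) / 100.0
    se = np.sqrt(p_tail * (1 - p_tail) / 600)
    assert abs(observed - p_tail) < 3 * se


# -- NJ trees ---------------------------------------------------------------

def _tree_tip_distances(newick: str):
    from skbio import TreeNode

    tree = TreeNode.read(_io.StringIO(newick))
    tips = sorted(t.name for t in tree.tips())
    dm = {}
    for a, b in itertools.combinations(tips, 2):
        dm[(a, b)] = tree.find(a).distance(tree.find(b))
    return dm


def test_two_sequences_single_edge():
    res = clonal.nj_tree(["CARDY", "CARDF"], ids=["a", "b"])
    d = clonal.normalized_edit_distance("CARDY", "CARDF")
    dm = _tree_tip_distances(res.newick)
    assert dm[("a", "b")] == pytest.approx(d)


def test_single_sequence_degenerate_tree():
    res = clonal.nj_tree(["CARDY"], ids=["only"])
    assert "only" in res.newick


def test_copy_cap_flag():
    res = clonal.nj_tree(["CARDY", "CARDF"], ids=["a", "b"], copy_counts=[120, 3])
    row = res.overlay.set_index("leaf_id").loc["a"]
    assert row["overlay"] == 50 and bool(row["capped"])
    row_b = res.overlay.set_index("leaf_id").loc["b"]
    assert row_b["overlay"] == 3 and not bool(row_b["capped"])


def test_nj_recovers_tip_distances_on_additive_matrix():
    """NJ is exact on additive matrices: tip-to-tip distances match input."""
    ids = list("ABCD")
    # tree ((A:1,B:2):0.5,(C:1.5,D:0.7))
    dm = np.array([
        [0.0, 3.0, 3.0, 2.2],
        [3.0, 0.0, 4.0, 3.2],
        [3.0, 4.0, 0.0, 2.2],
        [2.2, 3.2, 2.2, 0.0],
    ])
    newick = clonal.nj_newick(dm, ids)
    tips = _tree_tip_distances(newick)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                assert tips[(a, b)] == pytest.approx(dm[i, j], abs=1e-9)


def test_dendrogram_from_lineage(clonal_igh, db):
    _, res = clonal_igh
    lin = clonal.group_lineages(res.table)
    members = clonal.lineage_members(res.table, lin.iloc[0])
    tree = clonal.lineage_dendrogram(members, max_clonotypes=10)
    assert tree.newick.endswith(";")
    assert (tree.overlay["overlay"] <= 50).all()
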