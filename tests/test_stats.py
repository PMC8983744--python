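"""Repertoire statistics: usage, links, CDR3, diversity, rarefaction."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import bcrkit
from bcrkit import stats
from conftest import mk_table


# -- usage ------------------------------------------------------------------

def test_usage_simple_percentages():
    t = mk_table([{"v_call": c} for c in ("V1*01", "V1*01", "V2*01", "V3*01")])
    out = stats.usage_frequencies(t, "V")
    freqs = dict(zip(out["segment_id"], out["percent_frequency"]))
    assert freqs == {"V1*01": 50.0, "V2*01": 25.0, "V3*01": 25.0}
    assert abs(out["percent_frequency"].sum() - 100.0) < 1e-6


def test_usage_duplicate_weighting():
    t = mk_table([
        {"v_call": "V1*01", "duplicate_count": 3},
        {"v_call": "V2*01", "duplicate_count": 1},
    ])
    weighted = stats.usage_frequencies(t, "V", weight_by_duplicates=True)
    assert dict(zip(weighted["segment_id"], weighted["percent_frequency"])) == {
        "V1*01": 75.0, "V2*01": 25.0,
    }
    unweighted = stats.usage_frequencies(t, "V", weight_by_duplicates=False)
    assert (unweighted["percent_frequency"] == 50.0).all()


def test_usage_unassigned_d_excluded_from_denominator():
    t = mk_table([
        {"d_call": "D1*01"}, {"d_call": "D1*01"}, {"d_call": ""},
    ])
    out = stats.usage_frequencies(t, "D")
    assert out["percent_frequency"].tolist() == [100.0]
    assert out.attrs["n_unassigned"] == 1


def test_usage_empty_table_raises():
    with pytest.raises(ValueError):
        stats.usage_frequencies(mk_table([]).iloc[0:0], "V")


def test_usage_recovery_from_simulation(db):
    """Configured segment usage is recovered within 3 binomial SEs."""
    ids = [s.id for s in db.functional_segments("IGH", "V")][:3]
    usage = dict(zip(ids, (0.5, 0.3, 0.2)))
    cfg = bcrkit.SimulationConfig(
        n_reads=10_000, v_usage=usage, shm_rate=0.0, seed=31, identifiable=False
    )
    rep = bcrkit.simulate_repertoire(db, cfg)
    freqs = rep.truth["v_call"].value_counts(normalize=True)
    for seg, p in usage.items():
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(freqs[seg] - p) < 3 * se


# -- links and circos -------------------------------------------------------

def test_vdj_links_counts_and_frequencies():
    t = mk_table([
        {"v_call": "V1*01", "d_call": "D1*01", "j_call": "J1*01"},
        {"v_call": "V1*01", "d_call": "D1*01", "j_call": "J1*01"},
        {"v_call": "V2*01", "d_call": "D1*01", "j_call": "J2*01"},
    ])
    links = stats.vdj_links(t, level="gene")
    by_key = links.set_index(["v_group", "j_group"])
    assert by_key.loc[("V1", "J1"), "relative_frequency"] == pytest.approx(2 / 3)
    assert by_key.loc[("V2", "J2"), "relative_frequency"] == pytest.approx(1 / 3)
    assert links["relative_frequency"].sum() == pytest.approx(1.0)
    single = stats.vdj_links(t.iloc[[0]], level="gene")
    assert single["relative_frequency"].tolist() == [1.0]


def test_circos_roundtrip(tmp_path):
    t = mk_table([
        {"v_call": "V1*01", "j_call": "J1*01"},
        {"v_call": "V1*01", "j_call": "J1*01", "duplicate_count": 4},
        {"v_call": "V2*01", "j_call": "J2*01"},
    ])
    links = stats.vdj_links(t, level="gene")
    kar, lnk = tmp_path / "karyotype.txt", tmp_path / "links.txt"
    stats.circos_export(links, kar, lnk)
    back = stats.circos_import(lnk)
    merged = links.merge(back, on=["v_group", "d_group", "j_group"], suffixes=("", "_rt"))
    assert (merged["count"] == merged["count_rt"]).all()
    # ideogram sizes equal total observation counts
    sizes = {line.split()[2]: int(line.split()[5]) for line in open(kar)}
    assert sizes["V1"] == 5 and sizes["V2"] == 1


# -- CDR3 -------------------------------------------------------------------

def test_cdr3_mean_length():
    t = mk_table([{"cdr3_aa": "A" * 10}, {"cdr3_aa": "A" * 20}])
    hist = stats.cdr3_length_distribution(t)
    assert hist.attrs["mean_length"] == 15.00
    assert set(hist["length"]) == {10, 20}


def test_cdr3_single_bar_for_identical_reads():
    t = mk_table([{"cdr3_aa": "CARDY"}] * 4)
    hist = stats.cdr3_length_distribution(t)
    assert len(hist) == 1
    assert hist["count"].iloc[0] == 4


def test_cdr3_restricted_to_productive():
    t = mk_table([
        {"cdr3_aa": "A" * 10, "productive": True},
        {"cdr3_aa": "A" * 30, "productive": False},
    ])
    assert stats.cdr3_length_distribution(t).attrs["mean_length"] == 10.0


def test_aa_composition_frequencies():
    t = mk_table([{"cdr3_aa": "CAR"}, {"cdr3_aa": "CAK"}])
    comp = stats.aa_composition(t)
    assert comp["C"] == pytest.approx(1 / 3)
    assert comp["A"] == pytest.approx(1 / 3)
    assert comp["R"] == pytest.approx(1 / 6)
    assert comp["K"] == pytest.approx(1 / 6)
    assert comp.sum() == pytest.approx(1.0)
    # permutation invariance
    comp2 = stats.aa_composition(t.iloc[::-1])
    pd.testing.assert_series_equal(comp, comp2)


def test_aa_composition_empty_raises():
    t = mk_table([{"cdr3_aa": "", "productive": False}])
    with pytest.raises(ValueError):
        stats.aa_composition(t)


# -- N/P additions -----------------------------------------------------------

def test_np_point_mass_for_fixed_lengths(db):
    cfg = bcrkit.SimulationConfig(
        n_reads=50, shm_rate=0.0, seed=41, p_prob=0.0,
        trim_dist={"kind": "fixed", "value": 0},
        n_len_dist={"kind": "fixed", "value": 3},
        identifiable=False,
    )
    rep = bcrkit.simulate_repertoire(db, cfg)
    table = bcrkit.truth_to_rearrangement(rep.records, db, "IGH")
    hists = stats.np_addition_distribution(table)
    assert hists["n1"].index.tolist() == [3]
    assert hists["n1"].attrs["mean"] == 3.0
    zero = bcrkit.SimulationConfig(
        n_reads=20, shm_rate=0.0, seed=42, p_prob=0.0,
        trim_dist={"kind": "fixed", "value": 0},
        n_len_dist={"kind": "fixed", "value": 0},
        identifiable=False,
    )
    rep0 = bcrkit.simulate_repertoire(db, zero)
    t0 = bcrkit.truth_to_rearrangement(rep0.records, db, "IGH")
    assert stats.np_addition_distribution(t0)["n1"].index.tolist() == [0]


def test_geometric_n_mean_recovered(db):
    cfg = bcrkit.SimulationConfig(
        n_reads=10_000, shm_rate=0.0, seed=43, identifiable=False,
        n_len_dist={"kind": "geometric", "mean": 4.0},
    )
    rep = bcrkit.simulate_repertoire(db, cfg)
    observed = rep.truth["n1"].str.len().mean()
    se = math.sqrt(4.0 * 5.0 / 10_000)  # geometric variance m(1+m)
    assert abs(observed - 4.0) < 3 * se


# -- Shannon-Weaver diversity ----------------------------------------------

def test_shannon_single_species_is_zero():
    res = stats.shannon_index([7])
    assert res.h_prime == 0.0
    assert res.n_species == 1


def test_shannon_uniform_is_log_s():
    for s in (2, 5, 11):
        res = stats.shannon_index([4] * s)
        assert res.h_prime == pytest.approx(math.log(s), abs=1e-12)


def test_shannon_direct_evaluation():
    res = stats.shannon_index([5, 3, 2])
    expected = -(0.5 * math.log(0.5) + 0.3 * math.log(0.3) + 0.2 * math.log(0.2))
    assert res.h_prime == pytest.approx(expected, abs=1e-12)


def test_shannon_rejects_bad_input():
    with pytest.raises(ValueError):
        stats.shannon_index([])
    with pytest.raises(ValueError):
        stats.shannon_index([3, 0, 2])


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=30))
def test_shannon_properties(counts):
    """Permutation-invariant, bounded by ln S, agrees with scipy entropy."""
    res = stats.shannon_index(counts)
    perm = stats.shannon_index(list(reversed(counts)))
    assert res.h_prime == pytest.approx(perm.h_prime, abs=1e-12)
    assert 0.0 <= res.h_prime <= math.log(len(counts)) + 1e-12
    assert res.h_prime == pytest.approx(
        float(sps.entropy(np.array(counts, dtype=float))), abs=1e-10
    )
    uniform = stats.shannon_index([10] * len(counts))
    assert res.h_prime <= uniform.h_prime + 1e-12


# -- rarefaction ------------------------------------------------------------

def _toy_clonotype_table():
    return mk_table([
        {"cdr3_aa": "CAAAA"}, {"cdr3_aa": "CAAAA"}, {"cdr3_aa": "CAAAA"},
        {"cdr3_aa": "CBBBB"}, {"cdr3_aa": "CCCCC"},
    ])


def test_rarefaction_boundary_depths():
    t = _toy_clonotype_table()
    curve = stats.rarefaction_curve(t, [1, 5], replicates=10, rng=np.random.default_rng(1))
    assert curve.loc[curve["depth"] == 1, "mean_species"].iloc[0] == 1.0
    assert curve.loc[curve["depth"] == 5, "mean_species"].iloc[0] == 3.0


def test_rarefaction_matches_exhaustive_enumeration():
    """Mean distinct count at depth 2 equals the brute-force expectation."""
    t = _toy_clonotype_table()
    labels = ["A", "A", "A", "B", "C"]
    exact = np.mean([
        len(set(combo)) for combo in combinations(labels, 2)
    ])
    rng = np.random.default_rng(2)
    curve = stats.rarefaction_curve(t, [2], replicates=4000, rng=rng)
    observed = curve["mean_species"].iloc[0]
    assert abs(observed - exact) < 0.05


def test_rarefaction_monotone(db, clonal_igh):
    _, res = clonal_igh
    curve = stats.rarefaction_curve(
        res.table, [10, 50, 100, 300], replicates=5, rng=np.random.default_rng(3)
    )
    assert (curve["mean_species"].diff().dropna() >= 0).all()


# -- productive fraction -----------------------------------------------------

@pytest.mark.parametrize(
    "flags, expected",
    [([True] * 3, 100.0), ([False] * 2, 0.0), ([True, True, True, False], 75.0)],
)
def test_productive_fraction(flags, expected):
    t = mk_table([{"productive": f} for f in flags])
    assert stats.productive_fraction(t) == expected


def test_sample_diversity_units(clonal_igh):
    _, res = clonal_igh
    by_clonotype = stats.sample_diversity(res.table, unit="clonotype")
    by_read = stats.sample_diversity(res.table, unit="read")
    assert by_clonotype.n_species <= by_read.n_species
    assert 0 <= by_clonotype.h_prime <= math.log(by_clonotype.n_species)
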