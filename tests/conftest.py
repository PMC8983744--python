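"""Shared fixtures: toy germline, a micro germline with hand-checkable
sequences, and small simulated repertoires."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import bcrkit
from bcrkit.germline import GeneSegment, GermlineDatabase


@pytest.fixture(scope="session")
def db() -> GermlineDatabase:
    return bcrkit.toy_germline()


def _nostop_codons(n: int, pattern: str = "GAAGTTCCA") -> str:
    # deterministic stop-free filler, period 9 so frames stay stop-free
    s = (pattern * (n // 3 + 2))[: n * 3]
    return s


@pytest.fixture(scope="session")
def micro_db() -> GermlineDatabase:
    """Tiny hand-designed germline for junction arithmetic done on paper.

    V: 57 nt stop-free body + TGT (Cys anchor at 57) + "AC" tail -> ends
    "...AC", so an untrimmed V followed by "GT" shows a 2-nt P.
    """
    v_seq = _nostop_codons(19) + "TGT" + "AC"
    v2_seq = ("GATACC" * 12)[:57] + "TGT" + "AC"
    j_seq = "ACAGTA" + "TTT" + "GGT" + "GAAACC"
    d_seq = "GGGGTACGTAGG"
    return GermlineDatabase(
        [
            GeneSegment("VTOY1*01", "IGH", "V", v_seq, "functional",
                        anchor_offset=57, reading_frame=0),
            GeneSegment("VTOY2*01", "IGH", "V", v2_seq, "functional",
                        anchor_offset=57, reading_frame=0),
            GeneSegment("DTOY1*01", "IGH", "D", d_seq, "functional"),
            GeneSegment("JTOY1*01", "IGH", "J", j_seq, "functional",
                        anchor_offset=6, reading_frame=0),
        ]
    )


@pytest.fixture(scope="session")
def small_igh(db):
    """150 IGH reads without SHM, annotated, with truth."""
    cfg = bcrkit.SimulationConfig(n_reads=150, shm_rate=0.0, seed=101)
    rep = bcrkit.simulate_repertoire(db, cfg)
    res = bcrkit.annotate_reads(rep.reads, db, "IGH")
    return rep, res


@pytest.fixture(scope="session")
def clonal_igh(db):
    """Clonally expanded IGH sample with SHM, annotated."""
    cfg = bcrkit.SimulationConfig(n_reads=300, n_lineages=6, shm_rate=0.01, seed=202)
    rep = bcrkit.simulate_repertoire(db, cfg)
    res = bcrkit.annotate_reads(rep.reads, db, "IGH")
    return rep, res


def mk_table(rows: list[dict]) -> pd.DataFrame:
    """Minimal rearrangement table with sane defaults for stats tests."""
    defaults = {
        "sequence_id": None,
        "sequence": "ACGT",
        "locus": "IGH",
        "v_call": "IGHV1-1*01",
        "d_call": "IGHD1-1*01",
        "j_call": "IGHJ1*01",
        "cdr1_aa": "GFTF",
        "cdr2_aa": "ISGG",
        "cdr3_aa": "CARDY",
        "productive": True,
        "duplicate_count": 1,
        "np1": "",
        "np2": "",
        "np1_length": 0,
        "np2_length": 0,
        "bk_n1": "",
        "bk_n2": "",
        "bk_p_v": "",
        "bk_p_d5": "",
        "bk_p_d3": "",
        "bk_p_j": "",
        "bk_v_gstart": 0,
        "bk_v_gend": 300,
        "bk_v_mutations": "",
        "bk_v_mut_count": 0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["sequence_id"] = f"R{i + 1:03d}"
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)
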