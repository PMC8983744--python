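"""Readers and writers for the external formats the pipeline touches.

Rearrangement tables are AIRR-style TSVs (standard column names where
they exist, package-specific columns prefixed ``bk_``); the column list
and the package's coordinate/CDR3 conventions travel in a sidecar JSON
schema rather than as comments inside the TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

REQUIRED_COLUMNS = [
    "sequence_id",
    "sequence",
    "locus",
    "v_call",
    "j_call",
    "productive",
    "duplicate_count",
]

_BOOL_COLUMNS = ["productive", "bk_tie", "bk_cdr3_unresolved", "bk_j_motif_ok"]
_INT_COLUMNS = [
    "duplicate_count", "np1_length", "np2_length",
    "bk_v_trim", "bk_d_trim5", "bk_d_trim3", "bk_j_trim",
    "bk_v_start", "bk_v_end", "bk_d_start", "bk_d_end", "bk_j_start", "bk_j_end",
    "bk_v_gstart", "bk_v_gend", "bk_d_gstart", "bk_d_gend",
    "bk_j_gstart", "bk_j_gend", "bk_v_mut_count",
]
_FLOAT_COLUMNS = ["bk_v_identity"]

CONVENTIONS = {
    "coordinates": "0-based, half-open",
    "cdr3": "Cys104 codon included through the codon before the J anchor "
            "(Phe/Trp-118 excluded); 'junction' additionally includes the J anchor codon",
    "pn_split": "maximal palindromic P assigned first at untrimmed ends, remainder N",
}


class SchemaError(ValueError):
    """A rearrangement table does not match the expected schema."""


def write_rearrangement_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a rearrangement TSV plus a ``<path>.schema.json`` sidecar."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    schema = {
        "columns": list(table.columns),
        "required": REQUIRED_COLUMNS,
        "conventions": CONVENTIONS,
    }
    with open(str(path) + ".schema.json", "w") as fh:
        json.dump(schema, fh, indent=1)


def read_rearrangement_tsv(path: str | Path) -> pd.DataFrame:
    """Read a rearrangement TSV, validating required columns.

    Unknown columns are preserved as strings; an empty file with only a
    header yields an empty table.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"rearrangement table {path} missing required columns: {missing}")
    for col in _BOOL_COLUMNS:
        if col in table.columns:
            table[col] = table[col].map({"True": True, "False": False})
    for col in _INT_COLUMNS:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col]).astype(int) if len(table) else table[col]
    for col in _FLOAT_COLUMNS:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col]).astype(float) if len(table) else table[col]
    return table


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n{seq}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA as an ordered id -> sequence mapping (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
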