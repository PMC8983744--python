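"""Bundled toy germline reference, generated programmatically.

A small, internally consistent germline set used by the examples, the
demo pipeline and the test suite: random but fixed (seeded) segment
sequences with the structural features the annotator relies on — a
conserved Cys codon near the V 3' end, a Phe anchor followed by Gly on
each J, CDR1/CDR2 windows on V, no stop codons in frame on functional
segments.  It is synthetic and carries no relationship to any real IMGT
allele despite the IMGT-style names.
"""

from __future__ import annotations

import numpy as np

from .germline import GeneSegment, GermlineDatabase

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _codons(n: int, rng: np.random.Generator) -> str:
    return "".join(_CODONS[int(i)] for i in rng.integers(0, len(_CODONS), size=n))


def _bases(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=n))


def _make_v(seg_id: str, locus: str, functionality: str, rng) -> GeneSegment:
    # FR1 | CDR1 (codons 26..34) | FR2 | CDR2 (codons 50..58) | FR3 | Cys104 | tail
    n_pre = int(rng.integers(94, 98))  # codons before the anchor
    body = _codons(n_pre, rng)
    if functionality == "pseudogene":
        # plant an in-frame stop in FR3
        pos = 70 * 3
        body = body[:pos] + "TAA" + body[pos + 3 :]
    tail = _codons(2, rng)  # germline contribution to CDR3 beyond Cys
    seq = body + "TGT" + tail
    return GeneSegment(
        id=seg_id,
        locus=locus,
        segment_type="V",
        sequence=seq,
        functionality=functionality,
        anchor_offset=n_pre * 3,
        reading_frame=0,
        cdr1=(26 * 3, 34 * 3),
        cdr2=(50 * 3, 58 * 3),
    )


def _make_d(seg_id: str, rng) -> GeneSegment:
    length = int(rng.integers(14, 23))
    return GeneSegment(
        id=seg_id,
        locus="IGH",
        segment_type="D",
        sequence=_bases(length, rng),
        functionality="functional",
    )


def _make_j(seg_id: str, locus: str, rng) -> GeneSegment:
    n_pre = int(rng.integers(5, 8))  # codons before the anchor (CDR3 side)
    n_post = int(rng.integers(4, 6))  # FR4 codons after Gly119
    gly = "GGT" if locus == "IGH" else "GGG"
    seq = _codons(n_pre, rng) + "TTT" + gly + _codons(n_post, rng)
    return GeneSegment(
        id=seg_id,
        locus=locus,
        segment_type="J",
        sequence=seq,
        functionality="functional",
        anchor_offset=n_pre * 3,
        reading_frame=0,
    )


def toy_germline(seed: int = 20240, n_ighv: int = 8, n_ighd: int = 5, n_ighj: int = 4,
                 n_igkv: int = 5, n_igkj: int = 3) -> GermlineDatabase:
    """Build the toy germline database (deterministic for a given seed).

    One IGHV and one IGKV are labelled pseudogene (with an in-frame stop)
    so functionality filtering has something to exclude.
    """
    rng = np.random.default_rng(seed)
    segments = []
    for i in range(n_ighv):
        functionality = "pseudogene" if i == n_ighv - 1 else "functional"
        segments.append(_make_v(f"IGHV{i + 1}-10*01", "IGH", functionality, rng))
    for i in range(n_ighd):
        segments.append(_make_d(f"IGHD{i + 1}-5*01", rng))
    for i in range(n_ighj):
        segments.append(_make_j(f"IGHJ{i + 1}*01", "IGH", rng))
    for i in range(n_igkv):
        functionality = "pseudogene" if i == n_igkv - 1 else "functional"
        segments.append(_make_v(f"IGKV{i + 1}-20*01", "IGK", functionality, rng))
    for i in range(n_igkj):
        segments.append(_make_j(f"IGKJ{i + 1}*01", "IGK", rng))
    return GermlineDatabase(segments)
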