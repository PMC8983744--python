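"""T20-style humanness scoring of antibody variable regions.

The T20 score of a query variable-region amino-acid sequence is the mean
percent identity of its 20 best matches in a human antibody reference
set.  Here the hosted database lookup of the original method is replaced
by exhaustive global pairwise alignment against a user-supplied
reference FASTA, so scores are comparable within a run (and against the
published cutoffs only to the extent the reference set resembles the
original database).  Low-immunogenicity cutoffs: FR+CDR score above 79,
framework-only score above 86.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

T20_FULL_CUTOFF = 79.0
T20_FR_CUTOFF = 86.0


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def percent_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Percent identity of the best global alignment: matches / columns.

    BLOSUM62 scoring guides the alignment; identity counting scores it.
    """
    if not a or not b:
        return 0.0
    aligner = aligner or _aligner()
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


@dataclass
class HumannessResult:
    """T20 humanness of one query (either or both scoring modes)."""

    query_id: str
    t20_full: float | None = None
    t20_fr: float | None = None
    n_matches_used: int = 0
    short_reference_set: bool = False  # fewer than 20 references available
    pass_full: bool | None = None
    pass_fr: bool | None = None


def t20_score(
    query_aa: str,
    reference_set: dict[str, str],
    mode: str = "full",
    query_id: str = "query",
    top_n: int = 20,
) -> HumannessResult:
    """Mean percent identity of the top ``top_n`` reference matches.

    ``mode="full"`` scores the FR+CDR sequence against the 79 cutoff;
    ``mode="fr_only"`` expects framework-only sequences on both sides and
    uses the 86 cutoff.  With fewer than ``top_n`` references, all are
    used and the result is flagged.
    """
    if not reference_set:
        raise ValueError("reference set is empty")
    if mode not in ("full", "fr_only"):
        raise ValueError(f"unknown mode {mode!r}")
    aligner = _aligner()
    identities = sorted(
        (percent_identity(query_aa, ref, aligner) for ref in reference_set.values()),
        reverse=True,
    )
    used = identities[:top_n]
    score = float(sum(used) / len(used))
    result = HumannessResult(
        query_id=query_id,
        n_matches_used=len(used),
        short_reference_set=len(identities) < top_n,
    )
    if mode == "full":
        result.t20_full = score
        result.pass_full = score > T20_FULL_CUTOFF
    else:
        result.t20_fr = score
        result.pass_fr = score > T20_FR_CUTOFF
    return result


def framework_sequence(full_aa: str, cdr1: str, cdr2: str, cdr3: str) -> str:
    """Remove the CDR1/2/3 substrings (in order) from a variable-region
    amino-acid sequence, leaving the concatenated frameworks."""
    out = full_aa
    cursor = 0
    pieces = []
    for cdr in (cdr1, cdr2, cdr3):
        if not cdr:
            continue
        pos = out.find(cdr, cursor)
        if pos < 0:
            raise ValueError(f"CDR {cdr!r} not found in sequence")
        pieces.append(out[cursor:pos])
        cursor = pos + len(cdr)
    pieces.append(out[cursor:])
    return "".join(pieces)


def score_queries(
    queries: dict[str, str],
    reference_set: dict[str, str],
    mode: str = "full",
    top_n: int = 20,
) -> pd.DataFrame:
    """T20 scores for many queries; one row per query."""
    rows = []
    for qid, seq in queries.items():
        r = t20_score(seq, reference_set, mode=mode, query_id=qid, top_n=top_n)
        score = r.t20_full if mode == "full" else r.t20_fr
        passed = r.pass_full if mode == "full" else r.pass_fr
        rows.append(
            {
                "query_id": qid,
                "mode": mode,
                "t20_score": score,
                "n_matches_used": r.n_matches_used,
                "short_reference_set": r.short_reference_set,
                "passed_cutoff": passed,
            }
        )
    return pd.DataFrame(rows)
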