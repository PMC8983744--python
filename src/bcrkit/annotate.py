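"""V(D)J read annotation.

Assigns germline V/D/J segments to BCR reads by exact ungapped local
alignment, decomposes the junction(s) into trimmed ends, palindromic (P)
and non-templated (N) nucleotides, extracts CDR1/2/3, calls productivity
and lists somatic mutations on the V segment.  This is a deliberately
lightweight annotator for synthetic and desk-scale data, not an IgBlast
replacement: substitution-only divergence, no indels, no isotype calling.

Conventions
-----------
* Coordinates are 0-based half-open, both on reads and on germline
  segments.
* CDR3 runs from the first base of the conserved V cysteine codon
  (Cys104, included) up to but excluding the J anchor codon
  (Phe/Trp-118); the J anchor plus the following glycine (Gly119) are
  verified as a flanking motif.  The ``junction`` column additionally
  includes the J anchor codon.
* P/N split of inter-segment bases is greedy: the maximal palindromic P
  extension of each untrimmed germline end is assigned first, the
  remainder is N.  P can only exist at an untrimmed end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import _align
from .germline import GeneSegment, GermlineDatabase

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class AnnotationParams:
    """Thresholds and conventions used by the annotator.

    min_v_identity/min_v_span: a V call requires >= 70% identity over an
    aligned span of >= 50 nt, otherwise the read is unannotatable.
    min_d_match: minimum number of consecutive matching bases to call a D
    segment; below it the D is reported unassigned.
    p_maxlen: maximum palindromic extension length considered.
    """

    min_v_identity: float = 70.0
    min_v_span: int = 50
    min_j_identity: float = 70.0
    min_j_span: int = 8
    min_d_match: int = 5
    p_maxlen: int = 3


@dataclass
class AnnotatedRead:
    read_id: str
    sequence: str
    locus: str
    v_call: str = ""
    d_call: str = ""
    j_call: str = ""
    # read-coordinate intervals, 0-based half-open
    v_interval: tuple[int, int] | None = None
    d_interval: tuple[int, int] | None = None
    j_interval: tuple[int, int] | None = None
    # germline-coordinate intervals
    v_germ_interval: tuple[int, int] | None = None
    d_germ_interval: tuple[int, int] | None = None
    j_germ_interval: tuple[int, int] | None = None
    v_identity: float = 0.0
    j_identity: float = 0.0
    v_trim: int | None = None
    d_trim_5: int | None = None
    d_trim_3: int | None = None
    j_trim: int | None = None
    p_v: str = ""
    p_d5: str = ""
    p_d3: str = ""
    p_j: str = ""
    n1: str = ""
    n2: str = ""
    np1: str = ""
    np2: str = ""
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    junction: str = ""
    junction_aa: str = ""
    cdr1_aa: str = ""
    cdr2_aa: str = ""
    productive: bool = False
    v_mutations: list[tuple[int, str, str]] = field(default_factory=list)
    duplicate_count: int = 1
    tie: bool = False
    cdr3_unresolved: bool = False
    j_motif_ok: bool = False
    unannotatable: bool = False
    fail_reason: str = ""


class UnannotatableRead(Exception):
    """Raised internally when no segment call clears its threshold."""


def _translate(nt: str) -> str:
    if len(nt) % 3 != 0 or not nt:
        return ""
    return str(Seq(nt).translate())


def _p_left(gap: str, retained_end: str, p_maxlen: int) -> str:
    """P extension at the left edge of ``gap`` continuing an upstream
    segment whose retained sequence ends with ``retained_end``."""
    k = 0
    limit = min(len(gap), len(retained_end), p_maxlen)
    while k < limit and gap[k] == _COMP[retained_end[-1 - k]]:
        k += 1
    return gap[:k]


def _p_right(gap: str, retained_start: str, p_maxlen: int) -> str:
    """P extension at the right edge of ``gap`` preceding a downstream
    segment whose retained sequence starts with ``retained_start``."""
    k = 0
    limit = min(len(gap), len(retained_start), p_maxlen)
    while k < limit and gap[-1 - k] == _COMP[retained_start[k]]:
        k += 1
    return gap[len(gap) - k :] if k else ""


class Annotator:
    """Annotates reads of one locus against a germline database."""

    def __init__(self, db: GermlineDatabase, params: AnnotationParams | None = None):
        self.db = db
        self.params = params or AnnotationParams()
        self._index_cache: dict[tuple[str, str], tuple] = {}

    # -- segment indexing -------------------------------------------------
    def _index(self, locus: str, segment_type: str):
        key = (locus, segment_type)
        if key not in self._index_cache:
            segs = self.db.segments(locus, segment_type)
            if segs:
                mmax = max(len(s) for s in segs)
                mat = np.full((len(segs), mmax), 255, dtype=np.uint8)
                for i, s in enumerate(segs):
                    mat[i, : len(s)] = _align.encode(s.sequence)
                lens = np.array([len(s) for s in segs], dtype=np.int64)
            else:
                mat = np.zeros((0, 0), dtype=np.uint8)
                lens = np.zeros(0, dtype=np.int64)
            self._index_cache[key] = (segs, mat, lens)
        return self._index_cache[key]

    # -- segment assignment -----------------------------------------------
    def _best_segment(self, segs, mat, lens, read_arr):
        hits = _align.batch_best_local(mat, lens, read_arr)
        scores = [h[0] for h in hits]
        best = max(scores)
        winners = [i for i, sc in enumerate(scores) if sc == best]
        idx = winners[0]  # segs are id-sorted: lexicographic tie-break
        return segs[idx], hits[idx], len(winners) > 1

    def assign_segments(self, read: AnnotatedRead) -> None:
        """Fill V, J (and D for IGH) calls and alignment intervals.

        V is chosen by best ungapped local alignment over all V of the
        locus; J is then searched downstream of the V interval; D (IGH
        only) by longest exact common substring within the V-J gap.
        """
        p = self.params
        seq = read.sequence
        arr = _align.encode(seq)

        v_segs, v_mat, v_lens = self._index(read.locus, "V")
        if not v_segs:
            raise UnannotatableRead("no V segments for locus")
        v_seg, (score, g0, g1, r0, r1, nmatch), v_tie = self._best_segment(
            v_segs, v_mat, v_lens, arr
        )
        span = g1 - g0
        identity = 100.0 * nmatch / span if span else 0.0
        if span < p.min_v_span or identity < p.min_v_identity:
            raise UnannotatableRead(
                f"best V ({v_seg.id}) span {span} identity {identity:.1f} below threshold"
            )
        read.v_call = v_seg.id
        read.v_interval = (r0, r1)
        read.v_germ_interval = (g0, g1)
        read.v_identity = identity
        read.tie = v_tie

        j_segs, j_mat, j_lens = self._index(read.locus, "J")
        if not j_segs:
            raise UnannotatableRead("no J segments for locus")
        tail = arr[r1:]
        j_seg, (jscore, jg0, jg1, jr0, jr1, jnmatch), j_tie = self._best_segment(
            j_segs, j_mat, j_lens, tail
        )
        jspan = jg1 - jg0
        j_identity = 100.0 * jnmatch / jspan if jspan else 0.0
        if jspan < p.min_j_span or j_identity < p.min_j_identity:
            raise UnannotatableRead(
                f"best J ({j_seg.id}) span {jspan} identity {j_identity:.1f} below threshold"
            )
        read.j_call = j_seg.id
        read.j_interval = (r1 + jr0, r1 + jr1)
        read.j_germ_interval = (jg0, jg1)
        read.j_identity = j_identity
        read.tie = read.tie or j_tie

        if read.locus == "IGH":
            self._assign_d(read)

    def _assign_d(self, read: AnnotatedRead) -> None:
        gap_start = read.v_interval[1]
        gap_end = read.j_interval[0]
        gap = read.sequence[gap_start:gap_end]
        d_segs, _, _ = self._index(read.locus, "D")
        best = None  # (length, id, gap_pos, d_pos, seg)
        for seg in d_segs:  # id-sorted: ties keep the first (lexicographic)
            length, a_pos, b_pos = _align.longest_common_substring(gap, seg.sequence)
            if best is None or length > best[0]:
                best = (length, seg.id, a_pos, b_pos, seg)
        if best is None or best[0] < self.params.min_d_match:
            read.d_call = ""
            return
        length, _, a_pos, b_pos, seg = best
        read.d_call = seg.id
        read.d_interval = (gap_start + a_pos, gap_start + a_pos + length)
        read.d_germ_interval = (b_pos, b_pos + length)

    # -- junction decomposition --------------------------------------------
    def call_junction(self, read: AnnotatedRead) -> None:
        """Decompose inter-segment bases into trims, P and N regions."""
        p_max = self.params.p_maxlen
        seq = read.sequence
        v = self.db[read.v_call]
        j = self.db[read.j_call]
        read.v_trim = len(v) - read.v_germ_interval[1]
        read.j_trim = read.j_germ_interval[0]

        if read.locus == "IGH" and read.d_call:
            d = self.db[read.d_call]
            read.d_trim_5 = read.d_germ_interval[0]
            read.d_trim_3 = len(d) - read.d_germ_interval[1]
            gap1 = seq[read.v_interval[1] : read.d_interval[0]]
            gap2 = seq[read.d_interval[1] : read.j_interval[0]]
            read.np1, read.np2 = gap1, gap2
            read.p_v = _p_left(gap1, v.sequence, p_max) if read.v_trim == 0 else ""
            retained_d = d.sequence[read.d_germ_interval[0] : read.d_germ_interval[1]]
            read.p_d5 = (
                _p_right(gap1[len(read.p_v) :], d.sequence, p_max)
                if read.d_trim_5 == 0
                else ""
            )
            read.n1 = gap1[len(read.p_v) : len(gap1) - len(read.p_d5)]
            read.p_d3 = (
                _p_left(gap2, d.sequence, p_max) if read.d_trim_3 == 0 else ""
            )
            read.p_j = (
                _p_right(gap2[len(read.p_d3) :], j.sequence, p_max)
                if read.j_trim == 0
                else ""
            )
            read.n2 = gap2[len(read.p_d3) : len(gap2) - len(read.p_j)]
        else:
            gap1 = seq[read.v_interval[1] : read.j_interval[0]]
            read.np1, read.np2 = gap1, ""
            read.p_v = _p_left(gap1, v.sequence, p_max) if read.v_trim == 0 else ""
            read.p_j = (
                _p_right(gap1[len(read.p_v) :], j.sequence, p_max)
                if read.j_trim == 0
                else ""
            )
            read.n1 = gap1[len(read.p_v) : len(gap1) - len(read.p_j)]
            read.n2 = ""

    # -- CDR extraction and productivity ------------------------------------
    def extract_cdr3(self, read: AnnotatedRead) -> None:
        """Locate CDR3 between the V Cys104 codon and the J anchor codon."""
        v = self.db[read.v_call]
        j = self.db[read.j_call]
        vg0, vg1 = read.v_germ_interval
        jg0, jg1 = read.j_germ_interval
        anchor_in_v = vg0 <= v.anchor_offset and v.anchor_offset + 3 <= vg1
        anchor_in_j = jg0 <= j.anchor_offset and j.anchor_offset + 3 <= jg1
        if not (anchor_in_v and anchor_in_j):
            read.cdr3_unresolved = True
            return
        v_anchor = read.v_interval[0] + (v.anchor_offset - vg0)
        j_anchor = read.j_interval[0] + (j.anchor_offset - jg0)
        if j_anchor <= v_anchor:
            read.cdr3_unresolved = True
            return
        cys = _translate(read.sequence[v_anchor : v_anchor + 3])
        if cys == "*":
            read.cdr3_unresolved = True
            return
        read.cdr3_nt = read.sequence[v_anchor:j_anchor]
        read.cdr3_aa = _translate(read.cdr3_nt)
        read.junction = read.sequence[v_anchor : j_anchor + 3]
        read.junction_aa = _translate(read.junction)
        motif = _translate(read.sequence[j_anchor : j_anchor + 6])
        read.j_motif_ok = len(motif) == 2 and motif[0] in "FW" and motif[1] == "G"

        for attr, iv in (("cdr1_aa", v.cdr1), ("cdr2_aa", v.cdr2)):
            if iv is not None and vg0 <= iv[0] and iv[1] <= vg1:
                start = read.v_interval[0] + (iv[0] - vg0)
                setattr(read, attr, _translate(read.sequence[start : start + iv[1] - iv[0]]))

    def is_productive(self, read: AnnotatedRead) -> bool:
        """In-frame junction (anchors a multiple of 3 apart) and stop-free
        translation of the aligned V..J span."""
        if read.cdr3_unresolved or not read.cdr3_nt:
            return False
        if len(read.cdr3_nt) % 3 != 0:
            return False
        v = self.db[read.v_call]
        vg0 = read.v_germ_interval[0]
        frame_start = read.v_interval[0] + ((v.reading_frame - vg0) % 3)
        end = read.j_interval[1]
        span = read.sequence[frame_start : frame_start + 3 * ((end - frame_start) // 3)]
        aa = _translate(span)
        return bool(aa) and "*" not in aa

    def v_mutation_positions(self, read: AnnotatedRead) -> list[tuple[int, str, str]]:
        """Mismatches vs the aligned germline V, 0-based germline coords."""
        v = self.db[read.v_call]
        g0, g1 = read.v_germ_interval
        r0, _ = read.v_interval
        germ = v.sequence[g0:g1]
        obs = read.sequence[r0 : r0 + (g1 - g0)]
        return [
            (g0 + i, gb, ob)
            for i, (gb, ob) in enumerate(zip(germ, obs))
            if gb != ob
        ]

    # -- top level ----------------------------------------------------------
    def annotate_read(self, read_id: str, sequence: str, locus: str) -> AnnotatedRead:
        read = AnnotatedRead(read_id=read_id, sequence=sequence.upper(), locus=locus)
        try:
            self.assign_segments(read)
        except UnannotatableRead as exc:
            read.unannotatable = True
            read.fail_reason = str(exc)
            return read
        self.call_junction(read)
        self.extract_cdr3(read)
        read.productive = self.is_productive(read)
        read.v_mutations = self.v_mutation_positions(read)
        return read


def _mutations_to_str(muts: list[tuple[int, str, str]]) -> str:
    return ";".join(f"{pos}:{a}>{b}" for pos, a, b in muts)


def mutations_from_str(text: str) -> list[tuple[int, str, str]]:
    """Parse the ``pos:A>G;...`` encoding used in the rearrangement TSV."""
    if not text or (isinstance(text, float) and np.isnan(text)):
        return []
    out = []
    for item in str(text).split(";"):
        pos, change = item.split(":")
        a, b = change.split(">")
        out.append((int(pos), a, b))
    return out


def _to_row(r: AnnotatedRead) -> dict:
    def iv(pair, which):
        return pair[which] if pair is not None else -1

    return {
        "sequence_id": r.read_id,
        "sequence": r.sequence,
        "locus": r.locus,
        "v_call": r.v_call,
        "d_call": r.d_call,
        "j_call": r.j_call,
        "junction": r.junction,
        "junction_aa": r.junction_aa,
        "cdr3": r.cdr3_nt,
        "cdr3_aa": r.cdr3_aa,
        "cdr1_aa": r.cdr1_aa,
        "cdr2_aa": r.cdr2_aa,
        "productive": bool(r.productive),
        "duplicate_count": int(r.duplicate_count),
        "np1": r.np1,
        "np2": r.np2,
        "np1_length": len(r.np1),
        "np2_length": len(r.np2),
        "bk_n1": r.n1,
        "bk_n2": r.n2,
        "bk_p_v": r.p_v,
        "bk_p_d5": r.p_d5,
        "bk_p_d3": r.p_d3,
        "bk_p_j": r.p_j,
        "bk_v_trim": -1 if r.v_trim is None else r.v_trim,
        "bk_d_trim5": -1 if r.d_trim_5 is None else r.d_trim_5,
        "bk_d_trim3": -1 if r.d_trim_3 is None else r.d_trim_3,
        "bk_j_trim": -1 if r.j_trim is None else r.j_trim,
        "bk_v_start": iv(r.v_interval, 0),
        "bk_v_end": iv(r.v_interval, 1),
        "bk_d_start": iv(r.d_interval, 0),
        "bk_d_end": iv(r.d_interval, 1),
        "bk_j_start": iv(r.j_interval, 0),
        "bk_j_end": iv(r.j_interval, 1),
        "bk_v_gstart": iv(r.v_germ_interval, 0),
        "bk_v_gend": iv(r.v_germ_interval, 1),
        "bk_d_gstart": iv(r.d_germ_interval, 0),
        "bk_d_gend": iv(r.d_germ_interval, 1),
        "bk_j_gstart": iv(r.j_germ_interval, 0),
        "bk_j_gend": iv(r.j_germ_interval, 1),
        "bk_v_identity": round(r.v_identity, 6),
        "bk_v_mutations": _mutations_to_str(r.v_mutations),
        "bk_v_mut_count": len(r.v_mutations),
        "bk_tie": bool(r.tie),
        "bk_cdr3_unresolved": bool(r.cdr3_unresolved),
        "bk_j_motif_ok": bool(r.j_motif_ok),
    }


@dataclass
class AnnotationResult:
    table: pd.DataFrame
    n_input: int
    n_annotated: int
    n_unannotatable: int
    unannotatable_ids: list[str]


def annotate_reads(
    reads: Iterable[tuple[str, str]] | Mapping[str, str],
    db: GermlineDatabase,
    locus: str,
    params: AnnotationParams | None = None,
    collapse_duplicates: bool = False,
) -> AnnotationResult:
    """Annotate reads and return an AIRR-style rearrangement table.

    ``reads`` is an iterable of (id, sequence) pairs.  With
    ``collapse_duplicates`` identical sequences are annotated once and
    their multiplicity recorded in ``duplicate_count`` (copy number of
    identical annotated reads); the representative keeps the first id.
    Unannotatable reads are excluded from the table but counted.
    """
    if isinstance(reads, Mapping):
        reads = list(reads.items())
    else:
        reads = list(reads)
    ann = Annotator(db, params)

    groups: list[tuple[str, str, int]] = []
    if collapse_duplicates:
        seen: dict[str, int] = {}
        counts: list[int] = []
        for rid, seq in reads:
            key = seq.upper()
            if key in seen:
                counts[seen[key]] += 1
            else:
                seen[key] = len(groups)
                groups.append((rid, key, 0))
                counts.append(1)
        groups = [(rid, seq, counts[i]) for i, (rid, seq, _) in enumerate(groups)]
    else:
        groups = [(rid, seq, 1) for rid, seq in reads]

    rows = []
    failed: list[str] = []
    for rid, seq, count in groups:
        rec = ann.annotate_read(rid, seq, locus)
        if rec.unannotatable:
            failed.append(rid)
            continue
        rec.duplicate_count = count
        rows.append(_to_row(rec))
    table = pd.DataFrame(rows, columns=list(_to_row(AnnotatedRead("", "A", "IGH")).keys()))
    return AnnotationResult(
        table=table,
        n_input=len(reads),
        n_annotated=len(rows),
        n_unannotatable=len(failed),
        unannotatable_ids=failed,
    )
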