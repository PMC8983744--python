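"""Synthetic V(D)J repertoire generator with known ground truth.

Emulates the generative process behind an annotated BCR sequencing
sample: segment choice under configurable usage distributions,
exonucleolytic trimming of segment ends, palindromic (P) and
non-templated (N) junctional nucleotides, clonal lineage expansion, and
per-base somatic hypermutation (SHM) with a CDR-biased hotspot
multiplier.  Every emitted read carries a :class:`TruthRecord` from which
the read can be reconstructed byte-exactly.

Canonical junctions
-------------------
A junction decomposition is not identifiable in general: an N base that
happens to continue an adjacent germline segment (or a P palindrome)
cannot be distinguished from templated sequence.  With
``identifiable=True`` (the default) the generator rejection-samples
junctions until the greedy maximal-germline/maximal-P decomposition — the
same convention the annotator applies — reproduces the sampled truth, so
ground truth is unique and annotator recovery can be asserted exactly.
This also keeps the retained D segment long enough to be detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from ._align import COMPLEMENT
from .germline import GermlineDatabase

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}


def _comp(base: str) -> str:
    return base.translate(COMPLEMENT)


# -- length distributions --------------------------------------------------

def sample_length(dist: dict[str, Any], rng: np.random.Generator) -> int:
    """Sample a non-negative length from a distribution spec.

    Specs are plain dicts (YAML-friendly): ``{"kind": "fixed", "value": k}``,
    ``{"kind": "geometric", "mean": m}`` (support 0, 1, 2, ...) or
    ``{"kind": "uniform", "low": a, "high": b}`` (inclusive bounds).
    """
    kind = dist["kind"]
    if kind == "fixed":
        return int(dist["value"])
    if kind == "geometric":
        mean = float(dist["mean"])
        if mean <= 0:
            return 0
        p = 1.0 / (1.0 + mean)
        return int(rng.geometric(p) - 1)
    if kind == "uniform":
        return int(rng.integers(int(dist["low"]), int(dist["high"]) + 1))
    raise ValueError(f"unknown length distribution kind {kind!r}")


def dist_mean(dist: dict[str, Any]) -> float:
    kind = dist["kind"]
    if kind == "fixed":
        return float(dist["value"])
    if kind == "geometric":
        return float(dist["mean"])
    if kind == "uniform":
        return (float(dist["low"]) + float(dist["high"])) / 2.0
    raise ValueError(f"unknown length distribution kind {kind!r}")


# -- configuration ---------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of one simulated repertoire sample.

    Usage vectors are dicts mapping segment ids to probabilities (summing
    to 1); ``None`` means uniform over the functional segments of the
    locus.  ``trim_dist`` applies independently to every junction end,
    ``n_len_dist`` to every N insert.  ``shm_rate`` is the per-base
    substitution probability, multiplied by ``hotspot_multiplier`` inside
    CDR positions.  With ``n_lineages`` set, reads are copies of founder
    rearrangements (star topology: each copy mutates independently from
    the founder) with lineage sizes drawn from ``expansion_dist`` and
    apportioned to exactly ``n_reads``.
    """

    n_reads: int = 2000
    locus: str = "IGH"
    v_usage: dict[str, float] | None = None
    d_usage: dict[str, float] | None = None
    j_usage: dict[str, float] | None = None
    trim_dist: dict[str, Any] = field(default_factory=lambda: {"kind": "geometric", "mean": 2.0})
    p_prob: float = 0.5
    p_maxlen: int = 3
    n_len_dist: dict[str, Any] = field(default_factory=lambda: {"kind": "geometric", "mean": 4.0})
    shm_rate: float = 0.01
    hotspot_multiplier: float = 5.0
    n_lineages: int | None = None
    expansion_dist: dict[str, Any] = field(default_factory=lambda: {"kind": "geometric", "mean": 10.0})
    identifiable: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.locus not in ("IGH", "IGK"):
            raise ValueError(f"unknown locus {self.locus!r}")
        for name in ("v_usage", "d_usage", "j_usage"):
            usage = getattr(self, name)
            if usage is None:
                continue
            vals = np.array(list(usage.values()), dtype=float)
            if (vals < 0).any():
                raise ValueError(f"{name} has negative probabilities")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {vals.sum()!r})")
        if not 0.0 <= self.shm_rate <= 1.0:
            raise ValueError("shm_rate must be in [0, 1]")
        if self.hotspot_multiplier < 0:
            raise ValueError("hotspot_multiplier must be >= 0")
        if not 0.0 <= self.p_prob <= 1.0:
            raise ValueError("p_prob must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


# -- truth records ---------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth for one emitted read; reconstructs the read exactly."""

    read_id: str
    lineage_id: str
    v_call: str
    d_call: str  # "" for IGK
    j_call: str
    v_trim: int
    d_trim5: int
    d_trim3: int
    j_trim: int
    p_v: str
    p_d5: str
    p_d3: str
    p_j: str
    n1: str
    n2: str
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    sequence: str = ""

    def unmutated_sequence(self, db: GermlineDatabase) -> str:
        v = db[self.v_call].sequence
        j = db[self.j_call].sequence
        parts = [v[: len(v) - self.v_trim], self.p_v, self.n1]
        if self.d_call:
            d = db[self.d_call].sequence
            parts += [self.p_d5, d[self.d_trim5 : len(d) - self.d_trim3], self.p_d3,
                      self.n2, self.p_j]
        parts.append(j[self.j_trim :])
        return "".join(parts)

    def reconstruct(self, db: GermlineDatabase) -> str:
        seq = list(self.unmutated_sequence(db))
        for pos, _from, to in self.mutations:
            seq[pos] = to
        return "".join(seq)


# -- rearrangement ---------------------------------------------------------

def _usage_sampler(db, locus, segment_type, usage, rng):
    if usage is None:
        segs = db.functional_segments(locus, segment_type)
        if not segs:
            segs = db.segments(locus, segment_type)
        ids = [s.id for s in segs]
        probs = np.full(len(ids), 1.0 / len(ids)) if ids else np.array([])
    else:
        ids = sorted(usage)
        probs = np.array([usage[i] for i in ids], dtype=float)
    if len(ids) == 0:
        raise ValueError(f"no {segment_type} segments available for {locus}")
    cum = np.cumsum(probs)

    def draw() -> str:
        return ids[int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))]

    return draw


def _sample_p(seg_end: str, p_prob: float, p_maxlen: int, rng, side: str) -> str:
    """P nucleotides: reverse-complement palindromic extension of an
    untrimmed segment end (``side`` = which segment end is extended)."""
    if p_maxlen <= 0 or rng.random() >= p_prob:
        return ""
    k = int(rng.integers(1, p_maxlen + 1))
    k = min(k, len(seg_end))
    if side == "after":  # extends the 3' end of the upstream segment
        return "".join(_comp(seg_end[-1 - i]) for i in range(k))
    # "before": precedes the 5' end of the downstream segment
    return "".join(_comp(seg_end[k - 1 - i]) for i in range(k))


def _random_n(length: int, rng) -> str:
    if length <= 0:
        return ""
    return "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=length))


def simulate_rearrangement(
    db: GermlineDatabase,
    config: SimulationConfig,
    rng: np.random.Generator,
    annotator=None,
) -> TruthRecord:
    """Sample one unmutated V(D)J rearrangement.

    IGH reads are ``trimmedV + P? + N1 + P? + trimmedD + P? + N2 + P? +
    trimmedJ``; IGK reads have a single V-J junction.  Trims never remove
    the CDR3 anchor codons and always leave at least one D base.  With
    ``config.identifiable`` the junction is resampled until the greedy
    annotator decomposition reproduces it (canonical form).
    """
    config.validate()
    locus = config.locus
    has_d = locus == "IGH"
    draw_v = _usage_sampler(db, locus, "V", config.v_usage, rng)
    draw_j = _usage_sampler(db, locus, "J", config.j_usage, rng)
    draw_d = _usage_sampler(db, locus, "D", config.d_usage, rng) if has_d else None

    if annotator is None and config.identifiable:
        from .annotate import AnnotationParams, Annotator

        annotator = Annotator(db, AnnotationParams(p_maxlen=config.p_maxlen))

    v = db[draw_v()]
    j = db[draw_j()]
    d = db[draw_d()] if has_d else None

    max_v_trim = len(v) - (v.anchor_offset + 3)
    max_j_trim = j.anchor_offset

    for _ in range(1000):
        v_trim = sample_length(config.trim_dist, rng)
        j_trim = sample_length(config.trim_dist, rng)
        if v_trim > max_v_trim or j_trim > max_j_trim:
            continue
        if has_d:
            d_trim5 = sample_length(config.trim_dist, rng)
            d_trim3 = sample_length(config.trim_dist, rng)
            if d_trim5 + d_trim3 >= len(d):
                continue
        else:
            d_trim5 = d_trim3 = 0

        ret_v = v.sequence[: len(v) - v_trim]
        ret_j = j.sequence[j_trim:]
        p_v = _sample_p(ret_v, config.p_prob, config.p_maxlen, rng, "after") if v_trim == 0 else ""
        p_j = _sample_p(ret_j, config.p_prob, config.p_maxlen, rng, "before") if j_trim == 0 else ""
        n1 = _random_n(sample_length(config.n_len_dist, rng), rng)
        if has_d:
            ret_d = d.sequence[d_trim5 : len(d) - d_trim3]
            p_d5 = _sample_p(ret_d, config.p_prob, config.p_maxlen, rng, "before") if d_trim5 == 0 else ""
            p_d3 = _sample_p(ret_d, config.p_prob, config.p_maxlen, rng, "after") if d_trim3 == 0 else ""
            n2 = _random_n(sample_length(config.n_len_dist, rng), rng)
        else:
            p_d5 = p_d3 = n2 = ""

        truth = TruthRecord(
            read_id="",
            lineage_id="",
            v_call=v.id,
            d_call=d.id if has_d else "",
            j_call=j.id,
            v_trim=v_trim,
            d_trim5=d_trim5,
            d_trim3=d_trim3,
            j_trim=j_trim,
            p_v=p_v,
            p_d5=p_d5,
            p_d3=p_d3,
            p_j=p_j,
            n1=n1,
            n2=n2,
        )
        truth.sequence = truth.unmutated_sequence(db)
        if not config.identifiable:
            return truth
        if _decomposition_matches(annotator, truth, locus):
            return truth
    raise RuntimeError(
        f"could not sample an identifiable junction for {v.id}/{d.id if d else '-'}/{j.id} "
        "after 1000 attempts; check trim/N settings"
    )


def _decomposition_matches(annotator, truth: TruthRecord, locus: str) -> bool:
    rec = annotator.annotate_read("chk", truth.sequence, locus)
    if rec.unannotatable:
        return False
    same = (
        rec.v_call == truth.v_call
        and rec.j_call == truth.j_call
        and rec.v_trim == truth.v_trim
        and rec.j_trim == truth.j_trim
        and rec.p_v == truth.p_v
        and rec.p_j == truth.p_j
        and rec.n1 == truth.n1
    )
    if locus == "IGH":
        same = same and (
            rec.d_call == truth.d_call
            and rec.d_trim_5 == truth.d_trim5
            and rec.d_trim_3 == truth.d_trim3
            and rec.p_d5 == truth.p_d5
            and rec.p_d3 == truth.p_d3
            and rec.n2 == truth.n2
        )
    return same


# -- somatic hypermutation -------------------------------------------------

def apply_shm(
    sequence: str,
    cdr_mask: np.ndarray,
    shm_rate: float,
    hotspot_multiplier: float,
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Mutate each position independently; CDR positions at a multiplied rate.

    Every mutated position changes to a uniformly chosen *different*
    base.  Returns the mutated sequence and the 0-based positions,
    ascending.
    """
    n = len(sequence)
    if len(cdr_mask) != n:
        raise ValueError("cdr_mask length must equal sequence length")
    if n == 0 or shm_rate == 0.0:
        return sequence, []
    rates = np.where(cdr_mask, min(shm_rate * hotspot_multiplier, 1.0), shm_rate)
    hits = rng.random(n) < rates
    positions = np.flatnonzero(hits)
    if positions.size == 0:
        return sequence, []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    codes = np.array([_CODE[b] for b in arr[positions]], dtype=np.int64)
    new_codes = (codes + rng.integers(1, 4, size=positions.size)) % 4
    arr[positions] = _BASES[new_codes]
    return arr.tobytes().decode("ascii"), positions.tolist()


def cdr_mask_for(truth: TruthRecord, db: GermlineDatabase) -> np.ndarray:
    """Boolean mask of CDR positions (CDR1, CDR2, CDR3) on a truth read."""
    v = db[truth.v_call]
    j = db[truth.j_call]
    n = len(truth.sequence)
    mask = np.zeros(n, dtype=bool)
    v_end = len(v) - truth.v_trim
    for iv in (v.cdr1, v.cdr2):
        if iv is not None and iv[1] <= v_end:
            mask[iv[0] : iv[1]] = True
    cdr3_start = v.anchor_offset  # trims never reach the anchor
    cdr3_end = n - (len(j) - j.anchor_offset) + 3  # through the J anchor codon
    mask[cdr3_start:cdr3_end] = True
    return mask


# -- repertoire-level simulation -------------------------------------------

def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` into len(weights) parts."""
    weights = np.asarray(weights, dtype=float)
    raw = total * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


TRUTH_COLUMNS = [
    "read_id", "lineage_id", "v_call", "d_call", "j_call",
    "v_trim", "d_trim5", "d_trim3", "j_trim",
    "p_v", "p_d5", "p_d3", "p_j", "n1", "n2",
    "mutations", "n_mutations", "sequence",
]


@dataclass
class SimulatedRepertoire:
    reads: list[tuple[str, str]]
    truth: pd.DataFrame
    records: list[TruthRecord]


def simulate_repertoire(db: GermlineDatabase, config: SimulationConfig) -> SimulatedRepertoire:
    """Simulate a full sample of ``config.n_reads`` annotated-ready reads.

    With ``config.n_lineages`` set, that many founder rearrangements are
    sampled, lineage sizes are drawn from ``expansion_dist`` and
    apportioned so the sizes sum to exactly ``n_reads`` (a fixed
    expansion of k with n_reads = k * n_lineages gives exactly k copies
    per lineage); each copy then receives independent SHM from the
    founder.  Without it every read is its own founder/lineage.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    from .annotate import AnnotationParams, Annotator

    annotator = (
        Annotator(db, AnnotationParams(p_maxlen=config.p_maxlen))
        if config.identifiable
        else None
    )

    n_founders = config.n_lineages if config.n_lineages else config.n_reads
    founders = [
        simulate_rearrangement(db, config, rng, annotator=annotator)
        for _ in range(n_founders)
    ]
    if config.n_lineages:
        sizes = np.array(
            [max(1, sample_length(config.expansion_dist, rng)) for _ in founders]
        )
        counts = _apportion(sizes, config.n_reads)
    else:
        counts = np.ones(n_founders, dtype=int)

    reads: list[tuple[str, str]] = []
    records: list[TruthRecord] = []
    read_no = 0
    for f_idx, founder in enumerate(founders):
        lineage_id = f"L{f_idx + 1:04d}"
        mask = cdr_mask_for(founder, db)
        for _copy in range(int(counts[f_idx])):
            read_no += 1
            read_id = f"R{read_no:06d}"
            mutated, positions = apply_shm(
                founder.sequence, mask, config.shm_rate, config.hotspot_multiplier, rng
            )
            muts = [
                (pos, founder.sequence[pos], mutated[pos]) for pos in positions
            ]
            rec = TruthRecord(
                read_id=read_id,
                lineage_id=lineage_id,
                v_call=founder.v_call,
                d_call=founder.d_call,
                j_call=founder.j_call,
                v_trim=founder.v_trim,
                d_trim5=founder.d_trim5,
                d_trim3=founder.d_trim3,
                j_trim=founder.j_trim,
                p_v=founder.p_v,
                p_d5=founder.p_d5,
                p_d3=founder.p_d3,
                p_j=founder.p_j,
                n1=founder.n1,
                n2=founder.n2,
                mutations=muts,
                sequence=mutated,
            )
            records.append(rec)
            reads.append((read_id, mutated))

    truth = pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "lineage_id": r.lineage_id,
                "v_call": r.v_call,
                "d_call": r.d_call,
                "j_call": r.j_call,
                "v_trim": r.v_trim,
                "d_trim5": r.d_trim5,
                "d_trim3": r.d_trim3,
                "j_trim": r.j_trim,
                "p_v": r.p_v,
                "p_d5": r.p_d5,
                "p_d3": r.p_d3,
                "p_j": r.p_j,
                "n1": r.n1,
                "n2": r.n2,
                "mutations": ";".join(f"{p}:{a}>{b}" for p, a, b in r.mutations),
                "n_mutations": len(r.mutations),
                "sequence": r.sequence,
            }
            for r in records
        ],
        columns=TRUTH_COLUMNS,
    )
    return SimulatedRepertoire(reads=reads, truth=truth, records=records)


def truth_to_rearrangement(
    records: list[TruthRecord], db: GermlineDatabase, locus: str
) -> pd.DataFrame:
    """Build an annotate-compatible rearrangement table from ground truth.

    An oracle path: segment intervals are derived from the truth layout
    instead of alignment, then CDR extraction, productivity and mutation
    listing reuse the annotator's own rules.  Useful for exercising the
    statistics modules at scales where re-aligning every read would be
    wasteful, and for testing the annotator against an independent
    construction.
    """
    from .annotate import AnnotatedRead, Annotator, _to_row

    ann = Annotator(db)
    rows = []
    for t in records:
        v = db[t.v_call]
        j = db[t.j_call]
        v_len = len(v) - t.v_trim
        rec = AnnotatedRead(read_id=t.read_id, sequence=t.sequence, locus=locus)
        rec.v_call, rec.d_call, rec.j_call = t.v_call, t.d_call, t.j_call
        rec.v_interval = (0, v_len)
        rec.v_germ_interval = (0, v_len)
        j_start = len(t.sequence) - (len(j) - t.j_trim)
        rec.j_interval = (j_start, len(t.sequence))
        rec.j_germ_interval = (t.j_trim, len(j))
        if t.d_call:
            d = db[t.d_call]
            d_start = v_len + len(t.p_v) + len(t.n1) + len(t.p_d5)
            d_len = len(d) - t.d_trim5 - t.d_trim3
            rec.d_interval = (d_start, d_start + d_len)
            rec.d_germ_interval = (t.d_trim5, len(d) - t.d_trim3)
        rec.v_trim, rec.j_trim = t.v_trim, t.j_trim
        rec.d_trim_5, rec.d_trim_3 = (t.d_trim5, t.d_trim3) if t.d_call else (None, None)
        rec.p_v, rec.p_d5, rec.p_d3, rec.p_j = t.p_v, t.p_d5, t.p_d3, t.p_j
        rec.n1, rec.n2 = t.n1, t.n2
        rec.np1 = t.p_v + t.n1 + t.p_d5
        rec.np2 = t.p_d3 + t.n2 + t.p_j if t.d_call else ""
        ann.extract_cdr3(rec)
        rec.productive = ann.is_productive(rec)
        rec.v_mutations = [
            (pos, a, b) for pos, a, b in t.mutations if pos < v_len
        ]
        span = v_len
        rec.v_identity = 100.0 * (span - len(rec.v_mutations)) / span
        rows.append(_to_row(rec))
    return pd.DataFrame(rows)
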