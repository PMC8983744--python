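"""Germline V/D/J gene-segment references.

A :class:`GermlineDatabase` holds the gene segments a rearranged antibody
read is assembled from: variable (V), diversity (D, heavy chain only) and
joining (J) segments for the heavy (IGH) and kappa light (IGK) loci.  Each
V and J segment carries the 0-based offset of its conserved CDR3 anchor
codon — the second cysteine (Cys104) on V, the J-phenylalanine/tryptophan
(position 118) on J — which is all the downstream modules need to delimit
CDR3 without full IMGT unique numbering.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

LOCI = ("IGH", "IGK")
SEGMENT_TYPES = ("V", "D", "J")
FUNCTIONALITIES = ("functional", "ORF", "pseudogene")

METADATA_COLUMNS = [
    "id",
    "locus",
    "segment_type",
    "functionality",
    "anchor_offset",
    "reading_frame",
]
# optional nt coordinates of CDR1/CDR2 on V segments (0-based half-open)
OPTIONAL_COLUMNS = ["cdr1_start", "cdr1_end", "cdr2_start", "cdr2_end"]


class GermlineValidationError(ValueError):
    """A germline record violates a database invariant."""


@dataclass(frozen=True)
class GeneSegment:
    """One germline gene segment.

    Parameters
    ----------
    id : str
        Segment name, e.g. ``"IGHV3-13*01"`` (gene plus ``*``-allele).
    locus : str
        ``"IGH"`` or ``"IGK"``.
    segment_type : str
        ``"V"``, ``"D"`` or ``"J"``.
    sequence : str
        Nucleotide sequence over ``ACGT``.
    functionality : str
        IMGT-like label: ``functional``, ``ORF`` or ``pseudogene``.
    anchor_offset : int or None
        0-based offset of the first base of the conserved anchor codon:
        Cys104 for V segments, Phe/Trp-118 for J segments.  ``None`` for D.
    reading_frame : int or None
        Frame (0..2) of the translated product relative to the segment
        start (V) or such that the anchor codon is in frame (J).
    cdr1 : tuple(int, int) or None
        CDR1 nucleotide interval on V, 0-based half-open.
    cdr2 : tuple(int, int) or None
        CDR2 nucleotide interval on V.
    """

    id: str
    locus: str
    segment_type: str
    sequence: str
    functionality: str
    anchor_offset: int | None = None
    reading_frame: int | None = None
    cdr1: tuple[int, int] | None = None
    cdr2: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise GermlineValidationError(f"{self.id}: unknown locus {self.locus!r}")
        if self.segment_type not in SEGMENT_TYPES:
            raise GermlineValidationError(
                f"{self.id}: unknown segment_type {self.segment_type!r}"
            )
        if self.functionality not in FUNCTIONALITIES:
            raise GermlineValidationError(
                f"{self.id}: unknown functionality {self.functionality!r}"
            )
        if not self.sequence:
            raise GermlineValidationError(f"{self.id}: empty sequence")
        if set(self.sequence) - set("ACGT"):
            raise GermlineValidationError(
                f"{self.id}: sequence contains non-ACGT characters"
            )
        if self.segment_type in ("V", "J"):
            if self.anchor_offset is None:
                raise GermlineValidationError(
                    f"{self.id}: {self.segment_type} segment requires anchor_offset"
                )
            if not 0 <= self.anchor_offset <= len(self.sequence) - 3:
                raise GermlineValidationError(
                    f"{self.id}: anchor_offset {self.anchor_offset} outside sequence"
                )
            aa = str(Seq(self.anchor_codon).translate())
            if self.segment_type == "V" and aa != "C":
                raise GermlineValidationError(
                    f"{self.id}: V anchor codon {self.anchor_codon!r} is not Cys"
                )
            if self.segment_type == "J" and aa not in ("F", "W"):
                raise GermlineValidationError(
                    f"{self.id}: J anchor codon {self.anchor_codon!r} is not Phe/Trp"
                )
            if self.reading_frame not in (0, 1, 2):
                raise GermlineValidationError(
                    f"{self.id}: reading_frame must be 0, 1 or 2"
                )

    @property
    def anchor_codon(self) -> str:
        if self.anchor_offset is None:
            raise AttributeError(f"{self.id}: D segments have no anchor codon")
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]

    @property
    def gene(self) -> str:
        """Gene-level name (allele suffix ``*NN`` stripped)."""
        return self.id.split("*", 1)[0]

    @property
    def subfamily(self) -> str:
        """Subfamily-level name, e.g. ``IGHV3`` for ``IGHV3-13*01``."""
        return self.gene.split("-", 1)[0].split("/", 1)[0]

    def __len__(self) -> int:
        return len(self.sequence)


class GermlineDatabase:
    """Collection of :class:`GeneSegment`, indexed by id and (locus, type).

    Lookups return deterministic, id-sorted lists.
    """

    def __init__(self, segments: Iterable[GeneSegment]):
        self._by_id: dict[str, GeneSegment] = {}
        for seg in segments:
            if seg.id in self._by_id:
                raise GermlineValidationError(f"duplicate segment id {seg.id!r}")
            self._by_id[seg.id] = seg
        self._index: dict[tuple[str, str], list[GeneSegment]] = {}
        for key in ((lo, ty) for lo in LOCI for ty in SEGMENT_TYPES):
            self._index[key] = sorted(
                (s for s in self._by_id.values() if (s.locus, s.segment_type) == key),
                key=lambda s: s.id,
            )

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._by_id

    def __getitem__(self, segment_id: str) -> GeneSegment:
        try:
            return self._by_id[segment_id]
        except KeyError:
            raise KeyError(f"unknown germline segment {segment_id!r}") from None

    def ids(self) -> list[str]:
        return sorted(self._by_id)

    def segments(self, locus: str, segment_type: str) -> list[GeneSegment]:
        """All segments of a locus and type, id-sorted."""
        key = (locus, segment_type)
        if key not in self._index:
            raise KeyError(f"unknown locus/type {key!r}")
        return list(self._index[key])

    def functional_segments(
        self, locus: str, segment_type: str, include_orf: bool = False
    ) -> list[GeneSegment]:
        """Segments labelled ``functional`` (optionally also ``ORF``), id-sorted.

        Whether "potentially functional" germline sets include ORF-labelled
        segments varies between references, so ORF inclusion is a flag.
        """
        allowed = {"functional"} | ({"ORF"} if include_orf else set())
        return [s for s in self.segments(locus, segment_type) if s.functionality in allowed]


def load_germline(fasta_path: str | Path, metadata_path: str | Path) -> GermlineDatabase:
    """Load a germline database from a FASTA file plus a TSV metadata sidecar.

    The metadata TSV must carry columns ``id, locus, segment_type,
    functionality, anchor_offset, reading_frame`` (anchor/frame blank for D)
    and may carry CDR1/CDR2 nucleotide coordinates for V segments.  FASTA
    record ids and metadata rows must match one-to-one.
    """
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise GermlineValidationError(f"metadata missing columns: {missing_cols}")
    if meta["id"].duplicated().any():
        dup = sorted(meta.loc[meta["id"].duplicated(), "id"])
        raise GermlineValidationError(f"duplicate ids in metadata: {dup}")

    meta_ids = set(meta["id"])
    fasta_ids = set(records)
    if meta_ids != fasta_ids:
        raise GermlineValidationError(
            "FASTA/metadata mismatch; only in FASTA: "
            f"{sorted(fasta_ids - meta_ids)}; only in metadata: {sorted(meta_ids - fasta_ids)}"
        )

    segments = []
    for row in meta.itertuples(index=False):
        def _int(value: str) -> int | None:
            return int(value) if value != "" else None

        cdr1 = cdr2 = None
        if "cdr1_start" in meta.columns and getattr(row, "cdr1_start", "") != "":
            cdr1 = (int(row.cdr1_start), int(row.cdr1_end))
        if "cdr2_start" in meta.columns and getattr(row, "cdr2_start", "") != "":
            cdr2 = (int(row.cdr2_start), int(row.cdr2_end))
        segments.append(
            GeneSegment(
                id=row.id,
                locus=row.locus,
                segment_type=row.segment_type,
                sequence=records[row.id],
                functionality=row.functionality,
                anchor_offset=_int(row.anchor_offset),
                reading_frame=_int(row.reading_frame),
                cdr1=cdr1,
                cdr2=cdr2,
            )
        )
    return GermlineDatabase(segments)


def write_germline(
    db: GermlineDatabase, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a database back to FASTA + metadata TSV (inverse of load)."""
    with open(fasta_path, "w") as fh:
        for seg_id in db.ids():
            fh.write(f">{seg_id}\n{db[seg_id].sequence}\n")
    rows = []
    for seg_id in db.ids():
        s = db[seg_id]
        rows.append(
            {
                "id": s.id,
                "locus": s.locus,
                "segment_type": s.segment_type,
                "functionality": s.functionality,
                "anchor_offset": "" if s.anchor_offset is None else s.anchor_offset,
                "reading_frame": "" if s.reading_frame is None else s.reading_frame,
                "cdr1_start": "" if s.cdr1 is None else s.cdr1[0],
                "cdr1_end": "" if s.cdr1 is None else s.cdr1[1],
                "cdr2_start": "" if s.cdr2 is None else s.cdr2[0],
                "cdr2_end": "" if s.cdr2 is None else s.cdr2[1],
            }
        )
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def v_region_label(segment: GeneSegment, position: int) -> str:
    """FR/CDR label of a 0-based nucleotide position on a V segment.

    Positions at or beyond the Cys104 anchor are labelled CDR3 (the V
    contribution to CDR3); CDR1/CDR2 come from the segment's annotated
    intervals, everything else is framework.
    """
    if segment.segment_type != "V":
        raise ValueError("region labels are defined on V segments")
    if segment.anchor_offset is not None and position >= segment.anchor_offset:
        return "CDR3"
    for name, iv in (("CDR1", segment.cdr1), ("CDR2", segment.cdr2)):
        if iv is not None and iv[0] <= position < iv[1]:
            return name
    if segment.cdr1 is not None and position < segment.cdr1[0]:
        return "FR1"
    if segment.cdr2 is not None and position >= segment.cdr2[1]:
        return "FR3"
    return "FR2"
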