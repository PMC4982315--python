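"""Format-independent view of one alignment record.

Predicate evaluation never touches the BAM binding layer directly; it sees
a :class:`ReadView`, built here from a decoded record.  All coordinates in
a ReadView are 1-based inclusive (the SAM text convention users see in
genome viewers); the single conversion from pysam's 0-based half-open
convention happens in :func:`view_from_record` and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import pysam

__all__ = ["ReadView", "FilterStats", "MalformedRecord", "view_from_record",
           "REF_CONSUMING", "QUERY_CONSUMING"]

# CIGAR op classes by what they consume (op letters as in SAM)
REF_CONSUMING = frozenset("MDN=X")
QUERY_CONSUMING = frozenset("MIS=X")

_CIGAR_OPS = "MIDNSHP=X"


class MalformedRecord(ValueError):
    """A record whose fields are internally inconsistent; carries the name."""

    def __init__(self, qname: str, message: str):
        super().__init__(f"{qname}: {message}")
        self.qname = qname


@dataclass(frozen=True)
class ReadView:
    """One alignment record, as the query semantics see it.

    ``start``/``end`` are 1-based inclusive reference coordinates of the
    leftmost/rightmost aligned base; both are ``None`` for unmapped reads.
    ``seq`` is the stored sequence (reference orientation), ``None`` when
    the record stores ``*``.
    """

    flag: int
    qname: str
    ref_name: Optional[str]
    mate_ref_name: Optional[str]
    start: Optional[int]
    end: Optional[int]
    mapq: int
    cigar: Tuple[Tuple[str, int], ...]
    seq: Optional[str]
    read_group: Optional[str]

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    @property
    def is_mate_unmapped(self) -> bool:
        return bool(self.flag & 0x8)


@dataclass
class FilterStats:
    """Accepted/rejected accounting for one filtering run (or chain stage)."""

    accepted: int = 0
    rejected: int = 0
    label: str = ""

    @property
    def total(self) -> int:
        return self.accepted + self.rejected

    def __iadd__(self, other: "FilterStats") -> "FilterStats":
        self.accepted += other.accepted
        self.rejected += other.rejected
        return self


def view_from_record(rec: pysam.AlignedSegment) -> ReadView:
    """Build a :class:`ReadView` from a decoded pysam record.

    Raises :class:`MalformedRecord` when the stored sequence length does
    not match the CIGAR's query-consuming length; the engine decides
    whether that is fatal or a logged skip.
    """
    unmapped = bool(rec.flag & 0x4)
    cigar: Tuple[Tuple[str, int], ...] = ()
    if rec.cigartuples:
        cigar = tuple((_CIGAR_OPS[op], ln) for op, ln in rec.cigartuples)

    start = end = None
    if not unmapped and rec.reference_id >= 0:
        start = rec.reference_start + 1
        ref_len = sum(ln for op, ln in cigar if op in REF_CONSUMING)
        end = start + ref_len - 1 if ref_len else start

    seq = rec.query_sequence or None
    if seq is not None and cigar:
        q_len = sum(ln for op, ln in cigar if op in QUERY_CONSUMING)
        if q_len != len(seq):
            raise MalformedRecord(
                rec.query_name or "?",
                f"sequence length {len(seq)} does not match CIGAR "
                f"query length {q_len}")

    ref_name = None
    if rec.reference_id >= 0:
        ref_name = rec.reference_name
    mate_ref_name = None
    if rec.next_reference_id >= 0:
        mate_ref_name = rec.next_reference_name

    rg = None
    if rec.has_tag("RG"):
        rg = str(rec.get_tag("RG"))

    return ReadView(
        flag=rec.flag,
        qname=rec.query_name or "",
        ref_name=ref_name,
        mate_ref_name=mate_ref_name,
        start=start,
        end=end,
        mapq=rec.mapping_quality,
        cigar=cigar,
        seq=seq,
        read_group=rg,
    )
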