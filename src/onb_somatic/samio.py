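"""SAM reading/writing and PCR-duplicate flagging.

SAM text I/O is delegated to :mod:`pysam`; this module adapts records to the
lightweight :class:`AlignedRead` used throughout the toolkit and implements a
coordinate-key duplicate-flagging stand-in for Picard MarkDuplicates: among
reads sharing ``(contig, pos, strand, mate_pos)`` all but the first are
flagged and excluded from every downstream pileup and coverage computation.

Coordinates are 1-based inclusive everywhere in this package; conversion to
pysam's 0-based convention happens only at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

from .errors import SamFormatError

#: CIGAR operations understood by the toolkit. Only gapped-alignment ops are
#: modelled; clipping/padding ops are out of scope for pre-aligned reads.
OP_MATCH = "M"
OP_INS = "I"
OP_DEL = "D"

_QUERY_CONSUMING = {OP_MATCH, OP_INS}
_REF_CONSUMING = {OP_MATCH, OP_DEL}

# pysam integer cigar codes for M/I/D (and codes we map onto them)
_PYSAM_OP = {0: OP_MATCH, 1: OP_INS, 2: OP_DEL, 7: OP_MATCH, 8: OP_MATCH}


@dataclass
class AlignedRead:
    """One aligned read with 1-based coordinates and M/I/D gap operations."""

    name: str
    contig: str
    pos: int  # 1-based leftmost mapped position
    is_reverse: bool
    mapped: bool
    cigar: list[tuple[str, int]]
    bases: str
    quals: Sequence[int]
    mate_contig: str | None = None
    mate_pos: int | None = None
    tlen: int = 0
    is_duplicate: bool = False
    flags: int = field(default=0, repr=False)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_CONSUMING)

    def reference_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference position covered."""
        return self.pos + self.reference_consumed() - 1

    def validate(self) -> None:
        qc = self.query_consumed()
        if qc != len(self.bases) or len(self.bases) != len(self.quals):
            raise SamFormatError(
                f"read {self.name!r}: CIGAR consumes {qc} query bases but "
                f"sequence has {len(self.bases)} and {len(self.quals)} qualities"
            )


def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    cigar = []
    for code, length in rec.cigartuples or []:
        op = _PYSAM_OP.get(code)
        if op is None:
            raise SamFormatError(
                f"read {rec.query_name!r}: unsupported CIGAR op code {code}"
            )
        cigar.append((op, length))
    return AlignedRead(
        name=rec.query_name,
        contig=rec.reference_name or "*",
        pos=rec.reference_start + 1,
        is_reverse=rec.is_reverse,
        mapped=not rec.is_unmapped,
        cigar=cigar,
        bases=rec.query_sequence or "",
        quals=list(rec.query_qualities or []),
        mate_contig=rec.next_reference_name,
        mate_pos=(rec.next_reference_start + 1) if rec.next_reference_start >= 0 else None,
        tlen=rec.template_length,
        is_duplicate=rec.is_duplicate,
        flags=rec.flag,
    )


def read_sam(path: str) -> Iterator[AlignedRead]:
    """Stream :class:`AlignedRead` records from a SAM file in file order.

    Raises :class:`SamFormatError` for a missing header or for records whose
    CIGAR does not account for the stored sequence, reporting the offending
    line number.
    """
    try:
        handle = pysam.AlignmentFile(path, "r", check_sq=True)
    except ValueError as exc:
        raise SamFormatError(f"{path}: missing or invalid SAM header ({exc})") from exc
    with handle:
        n_header = str(handle.header).count("\n")
        n_records = 0
        records = iter(handle)
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except OSError as exc:  # htslib parse failure mid-file
                raise SamFormatError(
                    f"{path}: malformed record at line {n_header + n_records + 1} ({exc})"
                ) from exc
            n_records += 1
            read = _from_pysam(rec)
            try:
                read.validate()
            except SamFormatError as exc:
                raise SamFormatError(
                    f"{path}: line {n_header + n_records}: {exc}"
                ) from exc
            yield read


def write_sam(path: str, reads: Iterable[AlignedRead], contig_lengths: dict[str, int]) -> None:
    """Write reads as coordinate-ordered SAM with an @SQ header per contig."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        tid = {name: i for i, name in enumerate(contig_lengths)}
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.name
            rec.reference_id = tid[read.contig]
            rec.reference_start = read.pos - 1
            rec.cigarstring = "".join(f"{n}{op}" for op, n in read.cigar)
            rec.query_sequence = read.bases
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.quals)
            )
            rec.mapping_quality = 60
            flag = read.flags
            if read.is_reverse:
                flag |= 0x10
            if not read.mapped:
                flag |= 0x4
            if read.is_duplicate:
                flag |= 0x400
            rec.flag = flag
            if read.mate_contig is not None and read.mate_pos is not None:
                rec.next_reference_id = tid[read.mate_contig]
                rec.next_reference_start = read.mate_pos - 1
            rec.template_length = read.tlen
            out.write(rec)


def flag_duplicates(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Flag PCR duplicates by coordinate key, keeping the first of each group.

    Reads sharing ``(contig, pos, strand, mate_pos)`` are treated as copies of
    one template; every read after the first in input (coordinate) order has
    ``is_duplicate`` set. k identical pairs therefore yield k-1 flagged pairs.
    """
    seen: set[tuple] = set()
    out = []
    for read in reads:
        key = (read.contig, read.pos, read.is_reverse, read.mate_pos)
        if key in seen:
            read.is_duplicate = True
        else:
            seen.add(key)
        out.append(read)
    return out
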