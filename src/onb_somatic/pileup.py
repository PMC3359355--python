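"""Per-locus, per-strand pileups with zero-quality trimming.

A pileup column keeps forward- and reverse-strand base observations apart
because the genotype caller demands variant evidence from both strands.
Bases with Phred quality 0 are trimmed before the column is emitted, so no
downstream statistic ever sees them. Reads spanning a deletion contribute no
base observation at the deleted positions; insertions do not shift the
anchor. Overlapping mates are counted independently on their own strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import RangeError
from .samio import OP_DEL, OP_INS, OP_MATCH, AlignedRead


@dataclass
class PileupColumn:
    """Base observations over one reference position, split by strand."""

    contig: str
    pos: int  # 1-based
    ref_base: str
    forward: list[tuple[str, int]] = field(default_factory=list)  # (base, qual)
    reverse: list[tuple[str, int]] = field(default_factory=list)

    @property
    def depth_forward(self) -> int:
        return len(self.forward)

    @property
    def depth_reverse(self) -> int:
        return len(self.reverse)

    @property
    def depth(self) -> int:
        return len(self.forward) + len(self.reverse)

    def observations(self, strand: str | None = None) -> list[tuple[str, int]]:
        if strand == "+":
            return self.forward
        if strand == "-":
            return self.reverse
        return self.forward + self.reverse


def build_pileup(
    reads: Iterable[AlignedRead],
    contig: str,
    pos_range: tuple[int, int],
    reference: Mapping[str, str],
) -> Iterator[PileupColumn]:
    """Build pileup columns over ``pos_range`` (1-based inclusive).

    Unmapped and duplicate-flagged reads are skipped; zero-quality bases are
    trimmed. Yields a column for every position in the range, including
    zero-depth ones (empty observation lists).
    """
    if contig not in reference:
        raise RangeError(f"unknown contig {contig!r}")
    start, end = pos_range
    contig_len = len(reference[contig])
    if start < 1 or end > contig_len or start > end:
        raise RangeError(
            f"{contig}:{start}-{end} outside contig of length {contig_len}"
        )
    ref_seq = reference[contig]
    columns: dict[int, PileupColumn] = {
        p: PileupColumn(contig, p, ref_seq[p - 1]) for p in range(start, end + 1)
    }
    for read in reads:
        if not read.mapped or read.is_duplicate or read.contig != contig:
            continue
        _add_read(columns, read, start, end)
    for p in range(start, end + 1):
        yield columns[p]


def _add_read(columns: dict[int, PileupColumn], read: AlignedRead, start: int, end: int) -> None:
    ref_cursor = read.pos
    query_cursor = 0
    for op, length in read.cigar:
        if op == OP_MATCH:
            for i in range(length):
                p = ref_cursor + i
                if start <= p <= end:
                    q = read.quals[query_cursor + i]
                    if q >= 1:  # zero-quality bases trimmed from the pileup
                        col = columns[p]
                        obs = (read.bases[query_cursor + i], q)
                        (col.reverse if read.is_reverse else col.forward).append(obs)
            ref_cursor += length
            query_cursor += length
        elif op == OP_INS:
            query_cursor += length  # no anchor shift, no observation
        elif op == OP_DEL:
            ref_cursor += length  # deleted positions get no base observation


def write_pileup_tsv(path: str, columns: Iterable[PileupColumn]) -> None:
    """Export columns as TSV: contig, pos, ref, fwd bases/quals, rev bases/quals."""
    with open(path, "w") as out:
        out.write("contig\tpos\tref\tfwd_bases\tfwd_quals\trev_bases\trev_quals\n")
        for col in columns:
            fb = "".join(b for b, _ in col.forward)
            fq = ",".join(str(q) for _, q in col.forward)
            rb = "".join(b for b, _ in col.reverse)
            rq = ",".join(str(q) for _, q in col.reverse)
            out.write(f"{col.contig}\t{col.pos}\t{col.ref_base}\t{fb}\t{fq}\t{rb}\t{rq}\n")
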