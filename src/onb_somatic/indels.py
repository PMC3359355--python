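"""Two-step somatic indel detection.

Step one restricts the tumor to well-behaved templates by removing read
pairs whose insert size falls outside the open interval (50, 500), then
collects candidate indels from gapped alignment operations, left-normalizing
each event in repeat context and requiring a minimum number of supporting
reads. Step two inspects the matched normal across a window reaching 5 bases
upstream of the event start and 5 bases downstream of its end (boundaries
inclusive): the candidate is somatic only when the normal shows no
insertion or deletion operation intersecting that window. Windows with no
normal coverage are conservatively left non-somatic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .engine import ReadBlock, decode_bases
from .samio import OP_DEL, OP_INS, OP_MATCH, AlignedRead

INSERTION = "insertion"
DELETION = "deletion"

#: default tumor insert-size interval, open at both ends
DEFAULT_INSERT_INTERVAL = (50, 500)
#: bases added on each side of the event for the normal-sample test
NORMAL_WINDOW_PAD = 5


@dataclass(frozen=True)
class IndelCandidate:
    """A small insertion or deletion.

    ``start`` is the 1-based first affected reference base; for a deletion
    ``end`` is the last deleted base, for an insertion ``end == start`` is
    the anchor base after which the sequence is inserted.
    """

    contig: str
    start: int
    end: int
    kind: str  # insertion | deletion
    sequence: str
    supporting_reads: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("indel sequence must be non-empty")
        if self.kind == DELETION and self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"deletion span {self.start}-{self.end} does not match "
                f"sequence length {len(self.sequence)}"
            )
        if self.kind == INSERTION and self.end != self.start:
            raise ValueError("insertion must have end == start (anchor)")
        if self.kind not in (INSERTION, DELETION):
            raise ValueError(f"unknown indel kind {self.kind!r}")

    @property
    def size(self) -> int:
        return len(self.sequence)


@dataclass
class SomaticIndel:
    candidate: IndelCandidate
    normal_window: tuple[int, int]
    normal_indel_evidence: int
    normal_window_depth: int
    somatic: bool
    notes: list[str] = field(default_factory=list)


def left_normalize(ref_seq: str, candidate: IndelCandidate) -> IndelCandidate:
    """Shift an indel to its leftmost equivalent placement.

    A deletion of ``s..e`` may move one base left whenever the base at
    ``s-1`` equals the base at ``e`` (the deleted haplotype is unchanged);
    an insertion after anchor ``a`` may move left whenever its last inserted
    base equals the reference base at ``a``, rotating the sequence.
    """
    if candidate.kind == DELETION:
        s, e = candidate.start, candidate.end
        while s > 1 and ref_seq[s - 2] == ref_seq[e - 1]:
            s -= 1
            e -= 1
        return IndelCandidate(
            candidate.contig, s, e, DELETION, ref_seq[s - 1 : e],
            candidate.supporting_reads,
        )
    a = candidate.start
    seq = candidate.sequence
    while a > 1 and seq[-1] == ref_seq[a - 1]:
        seq = ref_seq[a - 1] + seq[:-1]
        a -= 1
    return IndelCandidate(
        candidate.contig, a, a, INSERTION, seq, candidate.supporting_reads
    )


# ----------------------------------------------------------------------
# step 1: insert-size filter and candidate discovery
# ----------------------------------------------------------------------

def filter_by_insert(
    reads: Iterable[AlignedRead],
    interval: tuple[int, int] = DEFAULT_INSERT_INTERVAL,
) -> list[AlignedRead]:
    """Keep reads with lo < |tlen| < hi (open interval); drop reads without
    a usable template length or mate position."""
    lo, hi = interval
    return [
        r
        for r in reads
        if r.mapped and r.mate_pos is not None and r.tlen != 0 and lo < abs(r.tlen) < hi
    ]


def filter_block_by_insert(
    block: ReadBlock, interval: tuple[int, int] = DEFAULT_INSERT_INTERVAL
) -> ReadBlock:
    lo, hi = interval
    t = np.abs(block.tlen)
    return block.subset((t > lo) & (t < hi) & (block.tlen != 0))


def _events_from_cigar(
    contig: str, pos: int, cigar: Sequence[tuple[str, int]], bases: str
) -> list[IndelCandidate]:
    events = []
    ref = pos
    query = 0
    for op, length in cigar:
        if op == OP_MATCH:
            ref += length
            query += length
        elif op == OP_DEL:
            # sequence filled from the reference by the caller
            events.append(("D", ref, length, None))
            ref += length
        elif op == OP_INS:
            anchor = ref - 1
            events.append(("I", anchor, length, bases[query : query + length]))
            query += length
    out = []
    for code, start, length, seq in events:
        if code == "D":
            out.append(IndelCandidate(contig, start, start + length - 1, DELETION, "N" * length))
        elif start >= 1:
            out.append(IndelCandidate(contig, start, start, INSERTION, seq))
    return out


def _raw_events(
    reads: Union[ReadBlock, Iterable[AlignedRead]], reference: Mapping[str, str]
) -> list[IndelCandidate]:
    raw: list[IndelCandidate] = []
    if isinstance(reads, ReadBlock):
        for i, cigar in reads.cigars.items():
            if reads.is_dup[i]:
                continue
            raw.extend(
                _events_from_cigar(
                    reads.contig, int(reads.pos[i]), cigar, decode_bases(reads.seq[i])
                )
            )
    else:
        for r in reads:
            if not r.mapped or r.is_duplicate:
                continue
            if any(op in (OP_INS, OP_DEL) for op, _ in r.cigar):
                raw.extend(_events_from_cigar(r.contig, r.pos, r.cigar, r.bases))
    # fill deletion sequences from the reference, then left-normalize
    out = []
    for ev in raw:
        if ev.kind == DELETION:
            ref_seq = reference[ev.contig]
            if ev.end > len(ref_seq):
                continue
            ev = IndelCandidate(
                ev.contig, ev.start, ev.end, DELETION, ref_seq[ev.start - 1 : ev.end]
            )
        out.append(left_normalize(reference[ev.contig], ev))
    return out


def discover_candidates(
    reads: Union[ReadBlock, Iterable[AlignedRead]],
    reference: Mapping[str, str],
    min_support: int = 2,
) -> list[IndelCandidate]:
    """One candidate per distinct left-normalized (contig, start, kind,
    sequence) with at least ``min_support`` supporting reads."""
    groups = Counter(
        (ev.contig, ev.start, ev.end, ev.kind, ev.sequence)
        for ev in _raw_events(reads, reference)
    )
    out = [
        IndelCandidate(contig, start, end, kind, seq, supporting_reads=n)
        for (contig, start, end, kind, seq), n in groups.items()
        if n >= min_support
    ]
    out.sort(key=lambda c: (c.contig, c.start, c.kind, c.sequence))
    return out


# ----------------------------------------------------------------------
# step 2: the normal-window test
# ----------------------------------------------------------------------

def _window_depth_block(block: ReadBlock, wstart: int, wend: int) -> int:
    # reads start at most read_length + 64 bases before the window can reach it
    # (64 bp of deletion slack is far beyond the modelled indel sizes)
    lo = int(np.searchsorted(block.pos, wstart - block.read_length - 64))
    hi = int(np.searchsorted(block.pos, wend, side="right"))
    n = 0
    for i in range(lo, hi):
        if block.is_dup[i]:
            continue
        if int(block.pos[i]) + block.reference_span(i) - 1 >= wstart:
            n += 1
    return n


def somatic_test(
    candidate: IndelCandidate,
    normal_reads: Union[ReadBlock, Iterable[AlignedRead]],
    reference: Mapping[str, str],
    pad: int = NORMAL_WINDOW_PAD,
) -> SomaticIndel:
    """Classify a tumor candidate using the matched normal.

    Counts insertion/deletion alignment operations in non-duplicate normal
    reads whose affected span intersects ``[start - pad, end + pad]``
    (inclusive). Somatic only when that count is zero; a window without any
    normal coverage is non-somatic with note ``no_normal_coverage``.
    """
    wstart = max(1, candidate.start - pad)
    wend = candidate.end + pad
    if isinstance(normal_reads, ReadBlock):
        if normal_reads.contig != candidate.contig:
            evidence, depth = 0, 0
        else:
            evidence = sum(
                1
                for ev in _raw_events(normal_reads, reference)
                if ev.contig == candidate.contig and ev.start <= wend and ev.end >= wstart
            )
            depth = _window_depth_block(normal_reads, wstart, wend)
    else:
        normal_reads = list(normal_reads)
        evidence = sum(
            1
            for ev in _raw_events(normal_reads, reference)
            if ev.contig == candidate.contig and ev.start <= wend and ev.end >= wstart
        )
        depth = sum(
            1
            for r in normal_reads
            if r.mapped
            and not r.is_duplicate
            and r.contig == candidate.contig
            and r.pos <= wend
            and r.end >= wstart
        )
    notes: list[str] = []
    if depth == 0:
        notes.append("no_normal_coverage")
        somatic = False
    else:
        somatic = evidence == 0
    return SomaticIndel(candidate, (wstart, wend), evidence, depth, somatic, notes)


def write_indel_tsv(path: str, candidates: Iterable[IndelCandidate]) -> None:
    """Candidates as TSV (contig, pos, kind, sequence, support)."""
    with open(path, "w") as out:
        out.write("contig\tpos\tkind\tsequence\tsupport\n")
        for c in candidates:
            out.write(f"{c.contig}\t{c.start}\t{c.kind}\t{c.sequence}\t{c.supporting_reads}\n")


def read_indel_tsv(path: str) -> list[IndelCandidate]:
    out = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:4] != ["contig", "pos", "kind", "sequence"]:
            raise ValueError(f"{path}: unexpected indel table header {header}")
        for line in handle:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            contig, pos, kind, seq = fields[:4]
            support = int(fields[4]) if len(fields) > 4 else 0
            start = int(pos)
            end = start + len(seq) - 1 if kind == DELETION else start
            out.append(IndelCandidate(contig, start, end, kind, seq, support))
    return out


def call_somatic_indels(
    tumor: Union[ReadBlock, Iterable[AlignedRead]],
    normal: Union[ReadBlock, Iterable[AlignedRead]],
    reference: Mapping[str, str],
    interval: tuple[int, int] = DEFAULT_INSERT_INTERVAL,
    min_support: int = 2,
    pad: int = NORMAL_WINDOW_PAD,
) -> list[SomaticIndel]:
    """Run both steps: insert filter, discovery, and the normal-window test."""
    if isinstance(tumor, ReadBlock):
        filtered: Union[ReadBlock, list[AlignedRead]] = filter_block_by_insert(tumor, interval)
    else:
        filtered = filter_by_insert(tumor, interval)
    if not isinstance(normal, ReadBlock):
        normal = list(normal)
    return [
        somatic_test(c, normal, reference, pad)
        for c in discover_candidates(filtered, reference, min_support)
    ]
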