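"""Vectorized read container and pileup/calling engine.

Whole-contig pileup construction one column object at a time is too slow for
tens of millions of base observations, so reads of uniform length are held in
a struct-of-arrays :class:`ReadBlock` (positions, strands, a base-code matrix
and a quality matrix). Per-strand, per-base observation counts and
quality-weight sums are accumulated with bincount over flat
``(position, strand, base)`` indices, and genotype calls are then made from
those aggregates with exactly the same decision rules as the streaming
caller in :mod:`onb_somatic.snv` (the quantized weights make the two paths
agree bit-for-bit; see ``snv.phred_weight``).

Reads containing insertions or deletions are the exception: their gapped
CIGARs live in a side table (``ReadBlock.cigars``) and are accumulated one
read at a time, which is cheap because gapped reads are rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import SamFormatError
from .samio import OP_DEL, OP_INS, OP_MATCH, AlignedRead
from .snv import (
    GENOTYPES,
    CallerThresholds,
    GenotypeCall,
    phred_weight,
)

BASES = "ACGT"
_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_TO_CODE[ord(_b)] = _i
    _BASE_TO_CODE[ord(_b.lower())] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: quality -> quantized weight lookup (Phred 0..93)
WEIGHT_LUT = np.array([phred_weight(q) for q in range(94)], dtype=np.float64)

_CHUNK_READS = 200_000


def encode_bases(seq: str) -> np.ndarray:
    return _BASE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode()


@dataclass
class ReadBlock:
    """Uniform-length aligned reads over one contig, column-major."""

    contig: str
    read_length: int
    pos: np.ndarray          # int64, 1-based leftmost mapped position
    is_reverse: np.ndarray   # bool
    is_read2: np.ndarray     # bool
    frag_id: np.ndarray      # int64 template identifier (mates share it)
    mate_pos: np.ndarray     # int64, 1-based
    tlen: np.ndarray         # int64 signed template length
    seq: np.ndarray          # (n, L) uint8 base codes
    qual: np.ndarray         # (n, L) uint8 Phred
    is_dup: np.ndarray = field(default=None)  # bool
    cigars: dict[int, list[tuple[str, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_dup is None:
            self.is_dup = np.zeros(len(self.pos), dtype=bool)

    def __len__(self) -> int:
        return len(self.pos)

    def sort_by_pos(self) -> None:
        order = np.argsort(self.pos, kind="stable")
        self._reorder(order)

    def _reorder(self, order: np.ndarray) -> None:
        inverse = np.empty_like(order)
        inverse[order] = np.arange(len(order))
        self.cigars = {int(inverse[i]): c for i, c in self.cigars.items()}
        for name in ("pos", "is_reverse", "is_read2", "frag_id", "mate_pos", "tlen", "is_dup"):
            setattr(self, name, getattr(self, name)[order])
        self.seq = self.seq[order]
        self.qual = self.qual[order]

    def subset(self, mask: np.ndarray) -> "ReadBlock":
        idx = np.nonzero(mask)[0]
        lookup = {int(old): new for new, old in enumerate(idx)}
        return ReadBlock(
            contig=self.contig,
            read_length=self.read_length,
            pos=self.pos[idx], is_reverse=self.is_reverse[idx],
            is_read2=self.is_read2[idx], frag_id=self.frag_id[idx],
            mate_pos=self.mate_pos[idx], tlen=self.tlen[idx],
            seq=self.seq[idx], qual=self.qual[idx], is_dup=self.is_dup[idx],
            cigars={lookup[i]: c for i, c in self.cigars.items() if i in lookup},
        )

    def cigar_of(self, i: int) -> list[tuple[str, int]]:
        return self.cigars.get(i, [(OP_MATCH, self.read_length)])

    def reference_span(self, i: int) -> int:
        return sum(n for op, n in self.cigar_of(i) if op in (OP_MATCH, OP_DEL))

    # ------------------------------------------------------------------
    # interop with the streaming representation
    # ------------------------------------------------------------------
    def to_reads(self) -> Iterator[AlignedRead]:
        for i in range(len(self)):
            name = f"frag_{self.contig}_{self.frag_id[i]}"
            yield AlignedRead(
                name=name,
                contig=self.contig,
                pos=int(self.pos[i]),
                is_reverse=bool(self.is_reverse[i]),
                mapped=True,
                cigar=self.cigar_of(i),
                bases=decode_bases(self.seq[i]),
                quals=self.qual[i].tolist(),
                mate_contig=self.contig,
                mate_pos=int(self.mate_pos[i]),
                tlen=int(self.tlen[i]),
                is_duplicate=bool(self.is_dup[i]),
                flags=0x1 | 0x2 | (0x80 if self.is_read2[i] else 0x40)
                | (0x20 if not self.is_reverse[i] else 0),
            )

    @classmethod
    def from_reads(cls, contig: str, reads: Sequence[AlignedRead]) -> "ReadBlock":
        reads = [r for r in reads if r.contig == contig and r.mapped]
        if not reads:
            raise ValueError(f"no mapped reads on {contig}")
        lengths = {len(r.bases) for r in reads}
        if len(lengths) != 1:
            raise SamFormatError("ReadBlock requires uniform read length")
        length = lengths.pop()
        n = len(reads)
        block = cls(
            contig=contig,
            read_length=length,
            pos=np.array([r.pos for r in reads], dtype=np.int64),
            is_reverse=np.array([r.is_reverse for r in reads], dtype=bool),
            is_read2=np.array([bool(r.flags & 0x80) for r in reads], dtype=bool),
            frag_id=np.arange(n, dtype=np.int64),
            mate_pos=np.array([r.mate_pos or 0 for r in reads], dtype=np.int64),
            tlen=np.array([r.tlen for r in reads], dtype=np.int64),
            seq=np.vstack([encode_bases(r.bases) for r in reads]),
            qual=np.array([list(r.quals) for r in reads], dtype=np.uint8),
            is_dup=np.array([r.is_duplicate for r in reads], dtype=bool),
        )
        for i, r in enumerate(reads):
            if r.cigar != [(OP_MATCH, length)]:
                block.cigars[i] = list(r.cigar)
        return block

    # ------------------------------------------------------------------
    # duplicate flagging (vectorized analogue of samio.flag_duplicates)
    # ------------------------------------------------------------------
    def flag_duplicates(self) -> None:
        """Set is_dup for all but the first read of each coordinate group.

        Groups share (pos, strand, mate_pos); stable sort preserves input
        order within a group, so the same reads are flagged as in the
        streaming implementation.
        """
        order = np.lexsort((self.mate_pos, self.is_reverse, self.pos))
        pos_s = self.pos[order]
        rev_s = self.is_reverse[order]
        mate_s = self.mate_pos[order]
        same = np.zeros(len(self), dtype=bool)
        if len(self) > 1:
            same[1:] = (
                (pos_s[1:] == pos_s[:-1])
                & (rev_s[1:] == rev_s[:-1])
                & (mate_s[1:] == mate_s[:-1])
            )
        dup = np.zeros(len(self), dtype=bool)
        dup[order] = same
        self.is_dup = dup


# ----------------------------------------------------------------------
# pileup aggregation
# ----------------------------------------------------------------------

def strand_base_aggregates(
    block: ReadBlock, contig_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate per-position (counts, weight sums) of shape (L, 2, 4).

    Axis 1 is strand (0 forward, 1 reverse), axis 2 the base code. Duplicate
    reads and zero-quality bases are excluded, deletions contribute nothing
    and inserted bases are skipped — identical semantics to
    :func:`onb_somatic.pileup.build_pileup`.
    """
    n_bins = contig_length * 8
    counts = np.zeros(n_bins, dtype=np.int64)
    wsum = np.zeros(n_bins, dtype=np.float64)
    keep = ~block.is_dup
    gapped = np.zeros(len(block), dtype=bool)
    if block.cigars:
        gapped[list(block.cigars)] = True

    simple_idx = np.nonzero(keep & ~gapped)[0]
    offsets = np.arange(block.read_length, dtype=np.int64)
    for lo in range(0, len(simple_idx), _CHUNK_READS):
        idx = simple_idx[lo : lo + _CHUNK_READS]
        p = (block.pos[idx, None] - 1) + offsets[None, :]
        b = block.seq[idx].astype(np.int64)
        q = block.qual[idx]
        s = block.is_reverse[idx, None].astype(np.int64)
        valid = (q >= 1) & (b < 4) & (p < contig_length)
        flat = ((p * 2 + s) * 4 + b)[valid]
        counts += np.bincount(flat, minlength=n_bins)
        wsum += np.bincount(flat, weights=WEIGHT_LUT[q[valid]], minlength=n_bins)

    for i in np.nonzero(keep & gapped)[0]:
        _accumulate_gapped(block, int(i), counts, wsum, contig_length)
    return counts.reshape(contig_length, 2, 4), wsum.reshape(contig_length, 2, 4)


def _accumulate_gapped(
    block: ReadBlock, i: int, counts: np.ndarray, wsum: np.ndarray, contig_length: int
) -> None:
    ref = int(block.pos[i]) - 1
    query = 0
    strand = int(block.is_reverse[i])
    for op, length in block.cigars[i]:
        if op == OP_MATCH:
            for j in range(length):
                p = ref + j
                b = int(block.seq[i, query + j])
                q = int(block.qual[i, query + j])
                if q >= 1 and b < 4 and p < contig_length:
                    flat = (p * 2 + strand) * 4 + b
                    counts[flat] += 1
                    wsum[flat] += WEIGHT_LUT[q]
            ref += length
            query += length
        elif op == OP_INS:
            query += length
        elif op == OP_DEL:
            ref += length


# ----------------------------------------------------------------------
# genotype calling from aggregates
# ----------------------------------------------------------------------

_EXPECTED = np.array([0.0, 0.5, 1.0])


def candidate_positions(
    counts: np.ndarray, ref_codes: np.ndarray, min_alt_per_strand: int = 1
) -> np.ndarray:
    """0-based positions with >= min_alt_per_strand non-reference
    observations on each strand — the only loci a variant call can survive."""
    length = counts.shape[0]
    pos_idx = np.arange(length)
    total = counts.sum(axis=2)  # (L, 2)
    ref_f = counts[pos_idx, 0, ref_codes]
    ref_r = counts[pos_idx, 1, ref_codes]
    alt_f = total[:, 0] - ref_f
    alt_r = total[:, 1] - ref_r
    return np.nonzero((alt_f >= min_alt_per_strand) & (alt_r >= min_alt_per_strand))[0]


def call_at_position(
    contig: str,
    pos0: int,
    ref_base: str,
    counts: np.ndarray,
    wsum: np.ndarray,
    thresholds: CallerThresholds,
    mode: str = "standard",
    alt: str | None = None,
) -> GenotypeCall:
    """Genotype call from one position's (2, 4) aggregate slices.

    Mirrors :func:`onb_somatic.snv.call_genotype`; the quantized weights make
    the two implementations numerically identical.
    """
    c = counts[pos0]
    w = wsum[pos0]
    ref_code = BASES.index(ref_base) if ref_base in BASES else -1
    notes: list[str] = []
    if alt is None:
        pooled_w = w[0] + w[1]
        best_code = -1
        best_w = 0.0
        for b in range(4):
            if b == ref_code:
                continue
            if pooled_w[b] > best_w:
                best_w = pooled_w[b]
                best_code = b
        if best_code >= 0:
            alt = BASES[best_code]
            notes = [
                f"minor_alt:{BASES[b]}"
                for b in sorted(
                    (b for b in range(4) if b not in (ref_code, best_code) and pooled_w[b] > 0),
                    key=lambda b: (-pooled_w[b], b),
                )
            ]
    alt_code = BASES.index(alt) if alt in BASES else -1

    depth_f = int(c[0].sum())
    depth_r = int(c[1].sum())
    if depth_f + depth_r == 0:
        return GenotypeCall(
            contig, pos0 + 1, ref_base, alt, None, None, None, None, None, None,
            "hom_ref", "no_call", notes + ["empty_column"],
        )

    total_f, total_r = float(w[0].sum()), float(w[1].sum())
    if alt_code >= 0:
        alt_f = w[0, alt_code] / total_f if depth_f else None
        alt_r = w[1, alt_code] / total_r if depth_r else None
    else:
        alt_f = 0.0 if depth_f else None
        alt_r = 0.0 if depth_r else None

    def best(p: float) -> tuple[int, float]:
        d = np.abs(p - _EXPECTED)
        g = int(np.argmin(d))  # first minimum: less variant genotype wins ties
        return g, float(d[g])

    geno_f, dist_f = best(alt_f) if alt_f is not None else (None, None)
    geno_r, dist_r = best(alt_r) if alt_r is not None else (None, None)

    pooled_total = total_f + total_r
    if alt_code >= 0:
        pooled_frac = float(w[0, alt_code] + w[1, alt_code]) / pooled_total
    else:
        pooled_frac = 0.0

    if mode == "variant_consensus" and alt_code >= 0:
        d_het = abs(pooled_frac - 0.5)
        d_hom = abs(pooled_frac - 1.0)
        geno_v, dist_v = (1, d_het) if d_het <= d_hom else (2, d_hom)
        if (
            dist_v <= thresholds.lenient_max_distance
            and c[0, alt_code] >= thresholds.min_alt_obs_per_strand
            and c[1, alt_code] >= thresholds.min_alt_obs_per_strand
        ):
            return GenotypeCall(
                contig, pos0 + 1, ref_base, alt,
                alt_f, alt_r,
                GENOTYPES[geno_f] if geno_f is not None else None,
                GENOTYPES[geno_r] if geno_r is not None else None,
                dist_f, dist_r, GENOTYPES[geno_v], "lenient", notes,
            )

    deep_enough = (
        depth_f >= thresholds.min_depth_per_strand
        and depth_r >= thresholds.min_depth_per_strand
    )
    if (
        geno_f is not None
        and geno_r is not None
        and geno_f == geno_r
        and dist_f <= thresholds.strict_max_distance
        and dist_r <= thresholds.strict_max_distance
        and deep_enough
    ):
        genotype, tier = GENOTYPES[geno_f], "high_quality"
    else:
        genotype, tier = GENOTYPES[best(pooled_frac)[0]], "no_call"
    return GenotypeCall(
        contig, pos0 + 1, ref_base, alt,
        alt_f, alt_r,
        GENOTYPES[geno_f] if geno_f is not None else None,
        GENOTYPES[geno_r] if geno_r is not None else None,
        dist_f, dist_r, genotype, tier, notes,
    )
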