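"""Synthetic tumor/normal whole-genome data generator.

Emulates the study design this toolkit targets: a small diploid genome,
germline SNPs at realistic density (transition-biased so the germline call
set shows a Ti/Tv near 2.1, with a configurable share of sites present in a
known-sites catalog standing in for dbSNP), somatic SNVs spiked at a chosen
variant-allele fraction, 1-7 bp germline and somatic indels, copy-gain and
single-copy-loss segments, and paired-end 100 bp reads with 300-350 bp
fragments, strand balance, a two-component base-quality mix including
zero-quality bases, and PCR duplicate pairs.

Reads are emitted pre-aligned at their true coordinates (alignment itself is
out of scope), with indel-carrying reads encoded through gapped M/I/D
alignment operations so the indel caller exercises real gap parsing.
Identical seed and configuration give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .annotate import GeneModel
from .engine import BASES, ReadBlock
from .errors import ConfigError
from .indels import DELETION, INSERTION, IndelCandidate, left_normalize

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults reflect the emulated study: 100 bp paired-end reads from
    300-350 bp fragments, 71X normal / 68X tumor coverage, ~85% of non-zero
    base qualities at Q30+, and a germline landscape whose called SNPs are
    ~87% known-site members with a transition/transversion ratio near 2.1.
    """

    seed: int = 0
    contig_lengths: tuple[int, ...] = (2_000_000, 2_000_000, 1_000_000)
    germline_snp_rate: float = 1e-3
    n_somatic_snvs: int = 200
    somatic_vaf: float = 0.5
    n_somatic_indels: int = 10
    n_germline_indels: int = 10
    indel_size_range: tuple[int, int] = (1, 7)
    cnv_segments: tuple[tuple[str, int, int, int], ...] = ()
    read_length: int = 100
    fragment_size_mean: float = 325.0
    fragment_size_sd: float = 20.0
    depth_normal: float = 71.0
    depth_tumor: float = 68.0
    base_error_rate: float = 1e-3
    zero_quality_rate: float = 0.01
    duplicate_rate: float = 0.05
    titv_target: float = 2.1
    known_site_fraction: float = 0.87
    n_genes: int = 40

    def __post_init__(self) -> None:
        rates = {
            "germline_snp_rate": self.germline_snp_rate,
            "somatic_vaf": self.somatic_vaf,
            "base_error_rate": self.base_error_rate,
            "zero_quality_rate": self.zero_quality_rate,
            "duplicate_rate": self.duplicate_rate,
            "known_site_fraction": self.known_site_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.somatic_vaf == 0.0 and self.n_somatic_snvs:
            raise ConfigError("somatic_vaf must be in (0, 1] when spiking SNVs")
        if any(length < 10_000 for length in self.contig_lengths):
            raise ConfigError("contig lengths must be >= 10 kb")
        if self.fragment_size_mean < self.read_length:
            raise ConfigError("fragment_size_mean must be >= read_length")
        lo, hi = self.indel_size_range
        if not 1 <= lo <= hi:
            raise ConfigError("indel_size_range must satisfy 1 <= lo <= hi")
        self._validate_cnv()

    def _validate_cnv(self) -> None:
        per_contig: dict[str, list[tuple[int, int]]] = {}
        names = set(self.contig_names())
        for contig, start, end, cn in self.cnv_segments:
            if contig not in names:
                raise ConfigError(f"CNV segment on unknown contig {contig!r}")
            if not (1 <= start <= end <= dict(zip(self.contig_names(), self.contig_lengths))[contig]):
                raise ConfigError(f"CNV segment {contig}:{start}-{end} outside contig")
            if cn < 0 or int(cn) != cn:
                raise ConfigError("tumor_copy_number must be a non-negative integer")
            per_contig.setdefault(contig, []).append((start, end))
        for contig, spans in per_contig.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ConfigError(f"overlapping CNV segments on {contig}")

    def contig_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.contig_lengths))]


@dataclass
class TruthTable:
    """Ground truth emitted alongside the reads (1-based positions)."""

    germline_snps: list[tuple[str, int, str, str, str]] = field(default_factory=list)
    somatic_snvs: list[tuple[str, int, str, str, float]] = field(default_factory=list)
    somatic_indels: list[IndelCandidate] = field(default_factory=list)
    germline_indels: list[tuple[IndelCandidate, str]] = field(default_factory=list)
    cnv_segments: list[tuple[str, int, int, int]] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    known_sites: set[tuple[str, int, str, str]] = field(default_factory=set)


# ----------------------------------------------------------------------
# reference + truth
# ----------------------------------------------------------------------

def simulate_reference(config: SimulationConfig) -> tuple[dict[str, str], TruthTable]:
    """Draw the reference genome and the full event truth table."""
    rng = np.random.default_rng([config.seed, 101])
    truth = TruthTable(cnv_segments=sorted(config.cnv_segments))
    reference: dict[str, str] = {}
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    edge = int(config.fragment_size_mean + 5 * config.fragment_size_sd)
    lo, hi = config.indel_size_range
    p_transition = config.titv_target / (config.titv_target + 1.0)

    for contig, length in zip(config.contig_names(), config.contig_lengths):
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        seq = base_arr[codes].tobytes().decode()
        reference[contig] = seq
        occupied = np.zeros(length + 2, dtype=bool)

        # germline SNPs: binomial thinning at the configured per-bp rate
        snp_pos = np.nonzero(rng.random(length) < config.germline_snp_rate)[0] + 1
        for pos in snp_pos.tolist():
            ref = seq[pos - 1]
            if rng.random() < p_transition:
                alt = _TRANSITION_OF[ref]
            else:
                alt = _TRANSVERSIONS_OF[ref][rng.integers(0, 2)]
            genotype = "het" if rng.random() < 2 / 3 else "hom"
            truth.germline_snps.append((contig, pos, ref, alt, genotype))
            occupied[pos] = True
            if rng.random() < config.known_site_fraction:
                truth.known_sites.add((contig, pos, ref, alt))

        # indels: spaced away from other events and contig edges
        def place_indel(size: int) -> tuple[int, int] | None:
            for _ in range(100):
                start = int(rng.integers(edge, length - edge - size))
                if not occupied[max(0, start - 10) : start + size + 11].any():
                    occupied[start : start + size + 1] = True
                    return start, start + size - 1
            return None

        n_per_contig = _split_count(config.n_germline_indels, config, contig)
        for _ in range(n_per_contig):
            size = int(rng.integers(lo, hi + 1))
            kind = DELETION if rng.random() < 0.5 else INSERTION
            placed = place_indel(size)
            if placed is None:
                continue
            start, end = placed
            if kind == DELETION:
                cand = IndelCandidate(contig, start, end, DELETION, seq[start - 1 : end])
            else:
                ins = "".join(BASES[i] for i in rng.integers(0, 4, size))
                cand = IndelCandidate(contig, start, start, INSERTION, ins)
            genotype = "het" if rng.random() < 2 / 3 else "hom"
            truth.germline_indels.append((left_normalize(seq, cand), genotype))

        for _ in range(_split_count(config.n_somatic_indels, config, contig)):
            size = int(rng.integers(lo, hi + 1))
            kind = DELETION if rng.random() < 0.5 else INSERTION
            placed = place_indel(size)
            if placed is None:
                continue
            start, end = placed
            if kind == DELETION:
                cand = IndelCandidate(contig, start, end, DELETION, seq[start - 1 : end])
            else:
                ins = "".join(BASES[i] for i in rng.integers(0, 4, size))
                cand = IndelCandidate(contig, start, start, INSERTION, ins)
            truth.somatic_indels.append(left_normalize(seq, cand))

        # somatic SNVs at positions free of germline events
        n_somatic = _split_count(config.n_somatic_snvs, config, contig)
        placed = 0
        while placed < n_somatic:
            pos = int(rng.integers(edge, length - edge))
            if occupied[pos]:
                continue
            occupied[pos] = True
            ref = seq[pos - 1]
            if rng.random() < p_transition:
                alt = _TRANSITION_OF[ref]
            else:
                alt = _TRANSVERSIONS_OF[ref][rng.integers(0, 2)]
            truth.somatic_snvs.append((contig, pos, ref, alt, config.somatic_vaf))
            placed += 1

    truth.genes = _simulate_genes(reference, config, rng)
    truth.germline_snps.sort()
    truth.somatic_snvs.sort()
    truth.somatic_indels.sort(key=lambda c: (c.contig, c.start))
    truth.germline_indels.sort(key=lambda item: (item[0].contig, item[0].start))
    return reference, truth


def _split_count(total: int, config: SimulationConfig, contig: str) -> int:
    """Deterministically apportion a genome-wide count over contigs by length."""
    lengths = dict(zip(config.contig_names(), config.contig_lengths))
    names = config.contig_names()
    genome = sum(lengths.values())
    counts = {}
    allotted = 0
    for name in names[:-1]:
        c = int(round(total * lengths[name] / genome))
        counts[name] = c
        allotted += c
    counts[names[-1]] = total - allotted
    return counts[contig]


def _simulate_genes(
    reference: Mapping[str, str], config: SimulationConfig, rng: np.random.Generator
) -> list[GeneModel]:
    """Toy single-transcript CDS models: 1-3 exons, total length a multiple
    of three, non-overlapping, random strand."""
    genes = []
    lengths = dict(zip(config.contig_names(), config.contig_lengths))
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    for i in range(config.n_genes):
        contig = config.contig_names()[int(rng.integers(0, len(lengths)))]
        length = lengths[contig]
        n_exons = int(rng.integers(1, 4))
        exon_lens = (3 * rng.integers(20, 120, size=n_exons)).tolist()
        intron_lens = rng.integers(50, 300, size=max(0, n_exons - 1)).tolist()
        span = sum(exon_lens) + sum(intron_lens)
        ok = False
        for _ in range(50):
            start = int(rng.integers(1000, length - span - 1000))
            if all(e < start or s > start + span for s, e in taken[contig]):
                ok = True
                break
        if not ok:
            continue
        taken[contig].append((start, start + span))
        exons = []
        cursor = start
        for j, el in enumerate(exon_lens):
            exons.append((cursor, cursor + el - 1))
            cursor += el + (intron_lens[j] if j < len(intron_lens) else 0)
        strand = "+" if rng.random() < 0.5 else "-"
        ordered = tuple(exons) if strand == "+" else tuple(exons[::-1])
        genes.append(GeneModel(f"GENE{i + 1:03d}", contig, strand, ordered))
    return genes


# ----------------------------------------------------------------------
# read-pair simulation
# ----------------------------------------------------------------------

def simulate_read_pairs(
    reference: Mapping[str, str],
    truth: TruthTable,
    config: SimulationConfig,
    sample: str,
) -> dict[str, ReadBlock]:
    """Simulate coordinate-sorted paired-end reads for 'tumor' or 'normal'.

    Fragment density scales with copy_number/2 inside tumor CNV segments;
    germline variants follow per-fragment haplotypes (het sites live on one
    of two haplotypes), somatic variants are carried by a fragment with
    probability equal to the configured VAF, and both mates of a fragment
    always agree on the template's alleles. Duplicate pairs replicate both
    mates' coordinates and alleles but are re-exposed to sequencing error.
    """
    if sample not in ("tumor", "normal"):
        raise ConfigError("sample must be 'tumor' or 'normal'")
    depth = config.depth_tumor if sample == "tumor" else config.depth_normal
    blocks = {}
    for ci, (contig, length) in enumerate(
        zip(config.contig_names(), config.contig_lengths)
    ):
        rng = np.random.default_rng(
            [config.seed, 1 if sample == "tumor" else 2, ci]
        )
        blocks[contig] = _simulate_contig(
            reference[contig], contig, length, truth, config, sample, depth, rng
        )
    return blocks


def _segment_partition(
    contig: str, length: int, truth: TruthTable, tumor: bool
) -> list[tuple[int, int, int]]:
    """(start, end, copy_number) partition of the contig; normal is diploid."""
    if not tumor:
        return [(1, length, 2)]
    segments = [
        (s, e, cn) for c, s, e, cn in truth.cnv_segments if c == contig
    ]
    segments.sort()
    out = []
    cursor = 1
    for s, e, cn in segments:
        if s > cursor:
            out.append((cursor, s - 1, 2))
        out.append((s, e, cn))
        cursor = e + 1
    if cursor <= length:
        out.append((cursor, length, 2))
    return out


def _simulate_contig(
    seq: str,
    contig: str,
    length: int,
    truth: TruthTable,
    config: SimulationConfig,
    sample: str,
    depth: float,
    rng: np.random.Generator,
) -> ReadBlock:
    rl = config.read_length
    ref_codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    ref_codes = lut[ref_codes]

    # --- fragments --------------------------------------------------------
    starts_list, lens_list = [], []
    for s, e, cn in _segment_partition(contig, length, truth, sample == "tumor"):
        expected = depth / (2 * rl) * (e - s + 1) * (cn / 2)
        n = rng.poisson(expected)
        if n == 0:
            continue
        starts_list.append(rng.integers(s, e + 1, size=n))
        lens_list.append(
            np.clip(
                np.rint(rng.normal(config.fragment_size_mean, config.fragment_size_sd, n)),
                rl,
                None,
            ).astype(np.int64)
        )
    frag_start = np.concatenate(starts_list)
    frag_len = np.concatenate(lens_list)
    frag_start = np.minimum(frag_start, length - frag_len + 1).astype(np.int64)
    frag_start = np.maximum(frag_start, 1)
    n_frag = len(frag_start)
    frag_rand = rng.integers(0, 2**64, size=n_frag, dtype=np.uint64)

    # PCR duplicates: resample existing templates so that the duplicate
    # fraction of all pairs is ~duplicate_rate
    d = config.duplicate_rate
    n_dup = rng.binomial(n_frag, d / (1 - d)) if d > 0 else 0
    if n_dup:
        src = rng.integers(0, n_frag, size=n_dup)
        frag_start = np.concatenate([frag_start, frag_start[src]])
        frag_len = np.concatenate([frag_len, frag_len[src]])
        frag_rand = np.concatenate([frag_rand, frag_rand[src]])
        n_frag += n_dup

    # --- reads (R1 forward at fragment start, R2 reverse at the end) ------
    r1_pos = frag_start
    r2_pos = frag_start + frag_len - rl
    pos = np.concatenate([r1_pos, r2_pos])
    is_read2 = np.zeros(2 * n_frag, dtype=bool)
    is_read2[n_frag:] = True
    mate_pos = np.concatenate([r2_pos, r1_pos])
    tlen = np.concatenate([frag_len, -frag_len])
    frag_id = np.concatenate([np.arange(n_frag)] * 2)
    hap_rand = np.concatenate([frag_rand, frag_rand])

    order = np.argsort(pos, kind="stable")
    pos, is_read2, mate_pos, tlen, frag_id, hap_rand = (
        a[order] for a in (pos, is_read2, mate_pos, tlen, frag_id, hap_rand)
    )

    n_reads = 2 * n_frag
    seq_mat = np.empty((n_reads, rl), dtype=np.uint8)
    offsets = np.arange(rl, dtype=np.int64)
    for lo in range(0, n_reads, 400_000):
        hi = min(lo + 400_000, n_reads)
        seq_mat[lo:hi] = ref_codes[(pos[lo:hi, None] - 1) + offsets[None, :]]

    cigars: dict[int, list[tuple[str, int]]] = {}

    # --- germline SNPs and somatic SNVs -----------------------------------
    for v_idx, (c, p, ref, alt, genotype) in enumerate(truth.germline_snps):
        if c != contig:
            continue
        rows = slice(
            np.searchsorted(pos, p - rl + 1), np.searchsorted(pos, p, side="right")
        )
        if rows.start >= rows.stop:
            continue
        carry = (
            np.ones(rows.stop - rows.start, dtype=bool)
            if genotype == "hom"
            else ((hap_rand[rows] >> np.uint64(v_idx % 61)) & np.uint64(1)).astype(bool)
        )
        cols = (p - pos[rows]).astype(np.int64)
        seq_mat[np.arange(rows.start, rows.stop)[carry], cols[carry]] = BASES.index(alt)

    if sample == "tumor":
        for c, p, ref, alt, vaf in truth.somatic_snvs:
            if c != contig:
                continue
            rows = slice(
                np.searchsorted(pos, p - rl + 1), np.searchsorted(pos, p, side="right")
            )
            if rows.start >= rows.stop:
                continue
            carry = _template_bernoulli(hap_rand[rows], np.uint64(p), vaf)
            cols = (p - pos[rows]).astype(np.int64)
            seq_mat[np.arange(rows.start, rows.stop)[carry], cols[carry]] = BASES.index(alt)

    # --- indels ------------------------------------------------------------
    events: list[tuple[IndelCandidate, str | float]] = [
        (cand, genotype) for cand, genotype in truth.germline_indels if cand.contig == contig
    ]
    if sample == "tumor":
        events += [
            (cand, config.somatic_vaf)
            for cand in truth.somatic_indels
            if cand.contig == contig
        ]
    for e_idx, (cand, carrier_rule) in enumerate(events):
        _spike_indel(
            cand, carrier_rule, e_idx, pos, hap_rand, seq_mat, cigars,
            ref_codes, rl, length,
        )

    # --- sequencing errors and base qualities ------------------------------
    total = n_reads * rl
    n_err = rng.binomial(total, config.base_error_rate)
    if n_err:
        flat = rng.integers(0, total, size=n_err)
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        seq_mat.reshape(-1)[flat] = (seq_mat.reshape(-1)[flat] + shift) % 4

    qual = np.empty((n_reads, rl), dtype=np.uint8)
    for lo in range(0, n_reads, 400_000):
        hi = min(lo + 400_000, n_reads)
        u = rng.random((hi - lo, rl))
        chunk = rng.integers(30, 41, size=(hi - lo, rl)).astype(np.uint8)
        low = u < config.zero_quality_rate + 0.15
        chunk[low] = rng.integers(2, 30, size=int(low.sum()))
        chunk[u < config.zero_quality_rate] = 0
        qual[lo:hi] = chunk

    return ReadBlock(
        contig=contig,
        read_length=rl,
        pos=pos.astype(np.int64),
        is_reverse=is_read2.copy(),
        is_read2=is_read2,
        frag_id=frag_id.astype(np.int64),
        mate_pos=mate_pos.astype(np.int64),
        tlen=tlen.astype(np.int64),
        seq=seq_mat,
        qual=qual,
        cigars=cigars,
    )


def _template_bernoulli(rand: np.ndarray, salt: np.uint64, p: float) -> np.ndarray:
    """Deterministic per-template Bernoulli(p): both mates of a fragment draw
    the same outcome (splitmix-style hash of the template's random word)."""
    salted = np.uint64((int(salt) * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF)
    x = rand ^ salted
    x = (x * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(31)
    return (x & np.uint64(0xFFFFFFFF)).astype(np.float64) / 2**32 < p


def _spike_indel(
    cand: IndelCandidate,
    carrier_rule,
    e_idx: int,
    pos: np.ndarray,
    hap_rand: np.ndarray,
    seq_mat: np.ndarray,
    cigars: dict[int, list[tuple[str, int]]],
    ref_codes: np.ndarray,
    rl: int,
    contig_length: int,
) -> None:
    """Rewrite carrier reads that fully span the event as gapped alignments."""
    k = cand.size
    if cand.kind == DELETION:
        s, e = cand.start, cand.end
        lo = int(np.searchsorted(pos, max(1, s - rl + 2)))
        hi = int(np.searchsorted(pos, s - 1, side="right"))
    else:
        a = cand.start
        lo = int(np.searchsorted(pos, max(1, a + k - rl + 2)))
        hi = int(np.searchsorted(pos, a, side="right"))
    if hi <= lo:
        return
    rows = np.arange(lo, hi)
    if carrier_rule == "hom":
        carry = np.ones(len(rows), dtype=bool)
    elif carrier_rule == "het":
        carry = ((hap_rand[rows] >> np.uint64((e_idx + 7) % 61)) & np.uint64(1)).astype(bool)
    else:  # somatic VAF
        carry = _template_bernoulli(
            hap_rand[rows], np.uint64(cand.start * 2 + 1), float(carrier_rule)
        )
    lut = {b: i for i, b in enumerate(BASES)}
    for row in rows[carry]:
        if int(row) in cigars:
            continue  # already carries another event; keep one gap per read
        p = int(pos[row])
        orig = seq_mat[row]
        if cand.kind == DELETION:
            if p - 1 + rl + k > contig_length:
                continue
            m1 = cand.start - p
            if m1 < 1 or m1 >= rl:
                continue
            # keep the read's own bases (with any spiked SNVs) around the gap;
            # only the k bases pulled in past the original read end come fresh
            # from the reference
            new = np.concatenate(
                [
                    orig[:m1],
                    orig[min(m1 + k, rl) :],
                    ref_codes[p - 1 + max(rl, m1 + k) : p - 1 + rl + k],
                ]
            )
            seq_mat[row] = new
            cigars[int(row)] = [("M", m1), ("D", k), ("M", rl - m1)]
        else:
            m1 = cand.start - p + 1
            if m1 < 1 or m1 + k > rl - 1:
                continue
            ins_codes = np.array([lut[b] for b in cand.sequence], dtype=np.uint8)
            new = np.concatenate([orig[:m1], ins_codes, orig[m1 : rl - k]])
            seq_mat[row] = new
            cigars[int(row)] = [("M", m1), ("I", k), ("M", rl - m1 - k)]
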