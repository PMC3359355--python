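"""Codon-level consequence annotation and call-set summary statistics.

Variants are mapped onto single-transcript CDS models (1-based inclusive
exon intervals, ordered 5'->3' in transcription direction), the affected
codon is read from the reference, mutated, and translated under the standard
genetic code. SNVs are classified synonymous / nsSNP / nonsense; coding
indels are frameshift unless their length is a multiple of three. Summary
statistics cover the transition/transversion ratio and the fraction of calls
present in a known-sites set (a dbSNP/1000 Genomes stand-in).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .indels import DELETION, INSERTION, IndelCandidate

# Standard genetic code, written out so consequence calls are self-contained;
# cross-checked against Biopython's translation table in the test suite.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_NSSNP = "nsSNP"
EFFECT_NONSENSE = "nonsense"
EFFECT_FRAMESHIFT = "frameshift"
EFFECT_INFRAME = "inframe_indel"
EFFECT_NON_CODING = "non_coding"


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript CDS model; exons ordered 5'->3' in transcription
    direction (genomically descending for minus-strand genes)."""

    name: str
    contig: str
    strand: str  # '+' | '-'
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.name}: strand must be + or -")
        for start, end in self.exons:
            if end < start:
                raise ValidationError(f"{self.name}: exon {start}-{end} reversed")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.name}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValidationError(f"{self.name}: exons not ordered 5'->3'")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


@dataclass(frozen=True)
class CodingConsequence:
    gene: str
    pos: int
    codon_index: int  # 1-based along the CDS
    position_in_codon: int  # 1-3
    ref_codon: str
    mut_codon: str
    ref_aa: str
    mut_aa: str
    effect: str


@dataclass
class VariantSummaryStats:
    n_snvs: int
    n_transitions: int
    n_transversions: int
    titv_ratio: float | None
    known_fraction: float


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cds_sequence(model: GeneModel, reference: Mapping[str, str]) -> str:
    ref = reference[model.contig]
    parts = []
    for start, end in model.exons:
        exon = ref[start - 1 : end]
        parts.append(exon if model.strand == "+" else reverse_complement(exon))
    return "".join(parts)


def map_to_codon(
    model: GeneModel, reference: Mapping[str, str], pos: int
) -> tuple[int, int, str] | None:
    """(codon_index, position_in_codon, reference codon) for a genomic
    position, or None when the position is non-coding for this model."""
    offset = 0
    hit = None
    for start, end in model.exons:
        if start <= pos <= end:
            within = (pos - start) if model.strand == "+" else (end - pos)
            hit = offset + within
            break
        offset += end - start + 1
    if hit is None:
        return None
    cds = cds_sequence(model, reference)
    codon_index = hit // 3 + 1
    position_in_codon = hit % 3 + 1
    codon = cds[3 * (codon_index - 1) : 3 * codon_index]
    return codon_index, position_in_codon, codon


def mutate_codon(ref_codon: str, position_in_codon: int, alt_base: str) -> str:
    """Substitute ``alt_base`` (given on the coding strand) at position 1-3."""
    if position_in_codon not in (1, 2, 3):
        raise ValueError("position_in_codon must be 1, 2 or 3")
    if ref_codon[position_in_codon - 1] == alt_base:
        raise ValueError("alternate base equals the reference base (no-op)")
    i = position_in_codon - 1
    return ref_codon[:i] + alt_base + ref_codon[i + 1 :]


def translate(codon: str) -> str:
    """Standard-code translation of one codon to a single-letter amino acid
    ('*' for stop)."""
    codon = codon.upper()
    if codon not in CODON_TABLE:
        raise ValidationError(f"cannot translate codon {codon!r}")
    return CODON_TABLE[codon]


def classify_effect(ref_codon: str, mut_codon: str) -> str:
    ref_aa = translate(ref_codon)
    mut_aa = translate(mut_codon)
    if mut_aa == ref_aa:
        return EFFECT_SYNONYMOUS
    if mut_aa == "*":
        return EFFECT_NONSENSE
    return EFFECT_NSSNP


def annotate_snv(
    models: Sequence[GeneModel],
    reference: Mapping[str, str],
    contig: str,
    pos: int,
    alt: str,
) -> CodingConsequence | None:
    """Full consequence for a genomic SNV, or None if non-coding for every
    model. Minus-strand models receive the complemented alternate base."""
    for model in models:
        if model.contig != contig:
            continue
        mapped = map_to_codon(model, reference, pos)
        if mapped is None:
            continue
        codon_index, pic, ref_codon = mapped
        coding_alt = alt if model.strand == "+" else alt.translate(_COMPLEMENT)
        if ref_codon[pic - 1] == coding_alt:
            continue  # no-op on the coding strand
        mut_codon = mutate_codon(ref_codon, pic, coding_alt)
        return CodingConsequence(
            gene=model.name,
            pos=pos,
            codon_index=codon_index,
            position_in_codon=pic,
            ref_codon=ref_codon,
            mut_codon=mut_codon,
            ref_aa=translate(ref_codon),
            mut_aa=translate(mut_codon),
            effect=classify_effect(ref_codon, mut_codon),
        )
    return None


def classify_indel_consequence(model: GeneModel, candidate: IndelCandidate) -> str:
    """frameshift / inframe_indel for CDS-overlapping indels, else non_coding."""
    if model.contig != candidate.contig:
        return EFFECT_NON_CODING
    if candidate.kind == DELETION:
        overlaps = any(
            s <= candidate.end and candidate.start <= e for s, e in model.exons
        )
    else:
        overlaps = model.contains(candidate.start)
    if not overlaps:
        return EFFECT_NON_CODING
    return EFFECT_INFRAME if len(candidate.sequence) % 3 == 0 else EFFECT_FRAMESHIFT


def summary_stats(
    snvs: Iterable[tuple[str, int, str, str]],
    known_sites: Iterable[tuple[str, int, str, str]] = (),
) -> VariantSummaryStats:
    """Ti/Tv and known-sites membership for biallelic SNVs given as
    (contig, pos, ref, alt) tuples."""
    known = set(known_sites)
    n = ti = matched = 0
    for contig, pos, ref, alt in snvs:
        n += 1
        if (ref, alt) in _TRANSITIONS:
            ti += 1
        if (contig, pos, ref, alt) in known:
            matched += 1
    tv = n - ti
    return VariantSummaryStats(
        n_snvs=n,
        n_transitions=ti,
        n_transversions=tv,
        titv_ratio=(ti / tv) if tv > 0 else None,
        known_fraction=(matched / n) if n else 0.0,
    )


# ----------------------------------------------------------------------
# gene-model TSV I/O (gene, contig, strand, exons as "start-end,start-end")
# ----------------------------------------------------------------------

def write_gene_models(path: str, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as out:
        out.write("gene\tcontig\tstrand\texons\n")
        for m in models:
            exons = ",".join(f"{s}-{e}" for s, e in m.exons)
            out.write(f"{m.name}\t{m.contig}\t{m.strand}\t{exons}\n")


def read_gene_models(path: str) -> list[GeneModel]:
    """Load models, rejecting (with a warning) any whose CDS length is not a
    multiple of three."""
    models = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:4] != ["gene", "contig", "strand", "exons"]:
            raise ValidationError(f"{path}: unexpected gene-model header {header}")
        for line in handle:
            if not line.strip():
                continue
            name, contig, strand, exons_s = line.rstrip("\n").split("\t")[:4]
            exons = tuple(
                (int(a), int(b))
                for a, b in (part.split("-") for part in exons_s.split(","))
            )
            model = GeneModel(name, contig, strand, exons)
            if model.cds_length % 3 != 0:
                warnings.warn(
                    f"{name}: CDS length {model.cds_length} not divisible by 3; skipped"
                )
                continue
            models.append(model)
    return models
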