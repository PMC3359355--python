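"""FASTA/VCF/BED writers and readers (pysam/Biopython at the boundary).

VCF records use explicit REF/ALT with the usual anchor-base convention for
indels. Coordinates are converted from the package's 1-based inclusive
convention at this boundary only.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .indels import DELETION, SomaticIndel
from .snv import SomaticSNV


def write_fasta(path: str, reference: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _vcf_header(contig_lengths: Mapping[str, int], info_lines: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    for line in info_lines:
        header.add_line(line)
    return header


def write_sites_vcf(
    path: str,
    sites: Iterable[tuple[str, int, str, str]],
    contig_lengths: Mapping[str, int],
    info: Mapping[tuple[str, int, str, str], Mapping[str, object]] | None = None,
    info_lines: Iterable[str] = (),
) -> None:
    """Write plain (contig, pos, ref, alt) site records, optionally with
    per-site INFO values."""
    header = _vcf_header(contig_lengths, info_lines)
    with pysam.VariantFile(path, "w", header=header) as out:
        for site in sorted(sites):
            contig, pos, ref, alt = site
            rec = out.new_record(
                contig=contig, start=pos - 1, stop=pos - 1 + len(ref),
                alleles=(ref, alt),
            )
            if info:
                for key, value in (info.get(site) or {}).items():
                    rec.info[key] = value
            out.write(rec)


def read_sites_vcf(path: str) -> set[tuple[str, int, str, str]]:
    """Biallelic SNV sites as (contig, pos, ref, alt)."""
    sites = set()
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1:
                    sites.add((rec.contig, rec.pos, rec.ref, alt))
    return sites


_SOMATIC_INFO_LINES = (
    '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic mutation">',
    '##INFO=<ID=TIER,Number=1,Type=String,Description="Call tier (high_quality or lenient)">',
    '##INFO=<ID=AF_FWD,Number=1,Type=Float,Description="Tumor forward-strand weighted alt fraction">',
    '##INFO=<ID=AF_REV,Number=1,Type=Float,Description="Tumor reverse-strand weighted alt fraction">',
    '##INFO=<ID=DIST_FWD,Number=1,Type=Float,Description="Forward-strand distance to best genotype">',
    '##INFO=<ID=DIST_REV,Number=1,Type=Float,Description="Reverse-strand distance to best genotype">',
    '##INFO=<ID=GT_TUMOR,Number=1,Type=String,Description="Tumor combined genotype">',
)


def write_somatic_snv_vcf(
    path: str, calls: Iterable[SomaticSNV], contig_lengths: Mapping[str, int]
) -> None:
    header = _vcf_header(contig_lengths, _SOMATIC_INFO_LINES)
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.contig, c.pos)):
            t = call.tumor
            if t.alt is None:
                continue
            rec = out.new_record(
                contig=t.contig, start=t.pos - 1, stop=t.pos, alleles=(t.ref, t.alt)
            )
            if call.somatic:
                rec.info["SOMATIC"] = True
            rec.info["TIER"] = t.tier
            rec.info["GT_TUMOR"] = t.genotype
            if t.alt_fraction_forward is not None:
                rec.info["AF_FWD"] = float(t.alt_fraction_forward)
            if t.alt_fraction_reverse is not None:
                rec.info["AF_REV"] = float(t.alt_fraction_reverse)
            if t.distance_forward is not None:
                rec.info["DIST_FWD"] = float(t.distance_forward)
            if t.distance_reverse is not None:
                rec.info["DIST_REV"] = float(t.distance_reverse)
            out.write(rec)


_INDEL_INFO_LINES = (
    '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic mutation">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Tumor reads supporting the indel">',
    '##INFO=<ID=NORMAL_EVIDENCE,Number=1,Type=Integer,Description="Indel operations in the normal window">',
)


def indel_to_vcf_alleles(
    indel, reference: Mapping[str, str]
) -> tuple[int, str, str]:
    """(pos, ref, alt) anchor-base encoding for an IndelCandidate."""
    seq = reference[indel.contig]
    if indel.kind == DELETION:
        anchor = indel.start - 1
        ref = seq[anchor - 1 : indel.end]
        return anchor, ref, ref[0]
    anchor = indel.start
    base = seq[anchor - 1]
    return anchor, base, base + indel.sequence


def write_somatic_indel_vcf(
    path: str,
    indels: Iterable[SomaticIndel],
    reference: Mapping[str, str],
    contig_lengths: Mapping[str, int],
) -> None:
    header = _vcf_header(contig_lengths, _INDEL_INFO_LINES)
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in sorted(indels, key=lambda c: (c.candidate.contig, c.candidate.start)):
            pos, ref, alt = indel_to_vcf_alleles(call.candidate, reference)
            rec = out.new_record(
                contig=call.candidate.contig,
                start=pos - 1,
                stop=pos - 1 + len(ref),
                alleles=(ref, alt),
            )
            if call.somatic:
                rec.info["SOMATIC"] = True
            rec.info["SUPPORT"] = call.candidate.supporting_reads
            rec.info["NORMAL_EVIDENCE"] = call.normal_indel_evidence
            out.write(rec)


def write_bed(path: str, intervals: Iterable[tuple[str, int, int, str]]) -> None:
    """1-based inclusive intervals written as 0-based half-open BED."""
    with open(path, "w") as out:
        for contig, start, end, name in intervals:
            out.write(f"{contig}\t{start - 1}\t{end}\t{name}\n")


def write_bedgraph(path: str, tracks) -> None:
    """Per-window normalized clone coverage as bedGraph (0-based half-open)."""
    with open(path, "w") as out:
        for track in tracks:
            ws = track.window_size
            for start1, value in zip(track.window_starts, track.normalized):
                out.write(f"{track.contig}\t{start1 - 1}\t{start1 - 1 + ws}\t{value:.4f}\n")
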