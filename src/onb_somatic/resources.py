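"""Packaged reference tables: the seven Sanger-validated codon changes, the
longitudinal codon observation matrix across archival samples, and the five
validated coding indels."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .indels import IndelCandidate


@dataclass(frozen=True)
class ValidatedSNVRecord:
    gene: str
    chrom: str
    position: int
    codon_index: int
    ref_codon: str
    ref_aa: str
    mut_codon: str
    mut_aa: str
    type: str
    sift: str      # external-predictor label, carried as an opaque string
    polyphen: str  # idem


def _data_path(name: str):
    return resources.files("onb_somatic.data").joinpath(name)


def validated_snv_records() -> list[ValidatedSNVRecord]:
    with _data_path("validated_snv_codons.tsv").open() as handle:
        return [
            ValidatedSNVRecord(
                gene=row["gene"],
                chrom=row["chrom"],
                position=int(row["position"]),
                codon_index=int(row["codon_index"]),
                ref_codon=row["ref_codon"],
                ref_aa=row["ref_aa"],
                mut_codon=row["mut_codon"],
                mut_aa=row["mut_aa"],
                type=row["type"],
                sift=row["sift"],
                polyphen=row["polyphen"],
            )
            for row in csv.DictReader(handle, delimiter="\t")
        ]


def longitudinal_matrix_path() -> str:
    return str(_data_path("longitudinal_codon_matrix.tsv"))


def validated_indel_records() -> list[IndelCandidate]:
    out = []
    with _data_path("validated_indels.tsv").open() as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            pos = int(row["pos"])
            kind = row["kind"]
            seq = row["sequence"]
            end = pos + len(seq) - 1 if kind == "deletion" else pos
            out.append(IndelCandidate(row["contig"], pos, end, kind, seq))
    return out
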