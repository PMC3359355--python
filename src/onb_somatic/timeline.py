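"""Longitudinal mutation-acquisition analysis.

Given a matrix of observed codons per archival sample at validated mutation
sites, each cell is classed mutant / reference / unknown (N/A), and every
site is classified along the sample timeline: *present_at_diagnosis* when
the earliest evaluable sample already shows the mutant codon, *acquired*
when the earliest evaluable sample is reference and a later sample turns
mutant, *inconsistent* for a mutant-then-reference reversion pattern, and
*never_observed* otherwise. Samples sharing a collection date are treated
as replicates: the mutation is present on that date if any replicate shows
the mutant codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date
from typing import Iterable

from .errors import ValidationError

NA_VALUES = {"N/A", "NA", ""}

PRESENT_AT_DIAGNOSIS = "present_at_diagnosis"
ACQUIRED = "acquired"
NEVER_OBSERVED = "never_observed"
INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class Sample:
    date: date
    site: str


@dataclass(frozen=True)
class Site:
    gene: str
    reference_codon: str
    mutant_codon: str


@dataclass
class PresenceMatrix:
    samples: list[Sample]  # ordered by date ascending
    sites: list[Site]
    cells: dict[tuple[int, int], str]  # (sample_idx, site_idx) -> codon or "N/A"

    def cell(self, sample: Sample, site: Site) -> str:
        return self.cells[(self.samples.index(sample), self.sites.index(site))]


@dataclass
class AcquisitionCall:
    gene: str
    status: str
    first_positive_sample: date | None


def _parse_date(text: str) -> date:
    return date.fromisoformat(text.strip())


def load_presence_matrix(path: str) -> PresenceMatrix:
    """Load a TSV observation matrix.

    Layout: header ``date<TAB>site<TAB><gene>...``; one row per sample with
    observed codons (or N/A); a final footer row whose date field is
    ``reference`` carrying each site's reference codon. The mutant codon of
    a site is the unique non-reference codon observed in its column; a cell
    matching neither the reference nor that mutant codon is a validation
    error naming the cell.
    """
    with open(path) as handle:
        rows = [line.rstrip("\n").split("\t") for line in handle if line.strip()]
    if len(rows) < 2:
        raise ValidationError(f"{path}: empty or header-only matrix")
    header = rows[0]
    if header[:2] != ["date", "site"]:
        raise ValidationError(f"{path}: expected 'date' and 'site' columns first")
    genes = header[2:]
    body = [r for r in rows[1:] if r[0] != "reference"]
    footer = [r for r in rows[1:] if r[0] == "reference"]
    if len(footer) != 1:
        raise ValidationError(f"{path}: expected exactly one reference footer row")
    ref_codons = footer[0][2:]
    if len(ref_codons) != len(genes):
        raise ValidationError(f"{path}: footer width does not match gene columns")

    parsed = []
    for row in body:
        if len(row) != len(header):
            raise ValidationError(f"{path}: row width mismatch in {row[:2]}")
        parsed.append((Sample(_parse_date(row[0]), row[1]), row[2:]))
    parsed.sort(key=lambda item: item[0].date)

    # infer each site's mutant codon as the unique non-reference codon observed
    sites = []
    for j, gene in enumerate(genes):
        observed = {
            obs[j].strip()
            for _, obs in parsed
            if obs[j].strip() not in NA_VALUES and obs[j].strip() != ref_codons[j]
        }
        if len(observed) > 1:
            raise ValidationError(
                f"{path}: column {gene} holds multiple non-reference codons {sorted(observed)}"
            )
        mutant = observed.pop() if observed else ref_codons[j]
        sites.append(Site(gene, ref_codons[j], mutant))

    cells = {}
    for i, (sample, obs) in enumerate(parsed):
        for j, site in enumerate(sites):
            value = obs[j].strip()
            if value in NA_VALUES:
                cells[(i, j)] = "N/A"
                continue
            if value not in (site.reference_codon, site.mutant_codon):
                raise ValidationError(
                    f"{path}: cell ({sample.date.isoformat()} {sample.site}, "
                    f"{site.gene}) codon {value!r} matches neither reference "
                    f"{site.reference_codon} nor mutant {site.mutant_codon}"
                )
            cells[(i, j)] = value
    return PresenceMatrix([s for s, _ in parsed], sites, cells)


def mutation_present(matrix: PresenceMatrix, sample: Sample, site: Site) -> str:
    """'mutant' | 'reference' | 'unknown' for one cell."""
    value = matrix.cell(sample, site)
    if value == "N/A":
        return "unknown"
    return "mutant" if value == site.mutant_codon else "reference"


def _presence_by_date(matrix: PresenceMatrix, site_idx: int) -> list[tuple[date, str]]:
    """Per-date status with same-date replicates merged (any mutant wins;
    all-N/A dates are unknown)."""
    by_date: dict[date, list[str]] = {}
    site = matrix.sites[site_idx]
    for i, sample in enumerate(matrix.samples):
        by_date.setdefault(sample.date, []).append(
            mutation_present(matrix, sample, site)
        )
    out = []
    for d in sorted(by_date):
        statuses = by_date[d]
        if "mutant" in statuses:
            out.append((d, "mutant"))
        elif "reference" in statuses:
            out.append((d, "reference"))
        else:
            out.append((d, "unknown"))
    return out


def classify_acquisition(matrix: PresenceMatrix) -> list[AcquisitionCall]:
    """Timeline classification for every site (see module docstring)."""
    calls = []
    for j, site in enumerate(matrix.sites):
        timeline = [
            (d, status) for d, status in _presence_by_date(matrix, j) if status != "unknown"
        ]
        if not timeline:
            warnings.warn(f"{site.gene}: all cells N/A; never evaluable")
            calls.append(AcquisitionCall(site.gene, NEVER_OBSERVED, None))
            continue
        statuses = [s for _, s in timeline]
        first_positive = next((d for d, s in timeline if s == "mutant"), None)
        if any(
            statuses[i] == "mutant" and "reference" in statuses[i + 1 :]
            for i in range(len(statuses))
        ):
            status = INCONSISTENT
        elif statuses[0] == "mutant":
            status = PRESENT_AT_DIAGNOSIS
        elif first_positive is not None:
            status = ACQUIRED
        else:
            status = NEVER_OBSERVED
        calls.append(AcquisitionCall(site.gene, status, first_positive))
    return calls


def acquisition_report(calls: Iterable[AcquisitionCall]) -> dict:
    """JSON-ready summary grouped by status."""
    report: dict[str, list] = {
        PRESENT_AT_DIAGNOSIS: [],
        ACQUIRED: [],
        NEVER_OBSERVED: [],
        INCONSISTENT: [],
    }
    for call in calls:
        entry = {"gene": call.gene}
        if call.first_positive_sample is not None:
            entry["first_positive_sample"] = call.first_positive_sample.isoformat()
        report[call.status].append(entry)
    return report
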