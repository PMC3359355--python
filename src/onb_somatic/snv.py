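"""Per-strand quality-weighted genotype calling and somatic classification.

The caller compares the observed allele mixture on each strand against the
three expected diploid genotype distributions (hom_ref, het, hom_alt with
alternate-allele fractions 0, 0.5, 1). On the two-point support {ref, alt}
the Kolmogorov-Smirnov sup-distance between the empirical and expected
distribution reduces to ``|p_hat - p_genotype|``, where ``p_hat`` is the
quality-weighted alternate fraction: each base contributes weight
``w = 1 - 10**(-Q/10)``, the probability its call is correct. A variant call
requires supporting evidence from both strands.

Two threshold tiers exist. The *standard* mode calls high-quality genotypes:
both strands must independently select the same genotype within the strict
distance. The *Variant Consensus* mode is the lenient tumor mode: it pools
the strands, accepts the best variant genotype within the lenient distance,
and demands a minimum number of alternate observations on each strand. A
tumor variant over a high-quality homozygous-reference normal genotype is
classified somatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import PairingError
from .pileup import PileupColumn

GENOTYPES = ("hom_ref", "het", "hom_alt")
#: Canonical diploid alternate-allele fractions per genotype.
EXPECTED_ALT_FRACTION = {"hom_ref": 0.0, "het": 0.5, "hom_alt": 1.0}
_VARIANT_GENOTYPES = ("het", "hom_alt")


@dataclass(frozen=True)
class CallerThresholds:
    """Distance/depth thresholds; strict tier must not exceed lenient."""

    strict_max_distance: float = 0.15
    lenient_max_distance: float = 0.25
    min_depth_per_strand: int = 4
    min_alt_obs_per_strand: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.strict_max_distance <= self.lenient_max_distance <= 1.0:
            raise ValueError("require 0 <= strict_max_distance <= lenient_max_distance <= 1")


@dataclass
class GenotypeCall:
    contig: str
    pos: int
    ref: str
    alt: str | None
    alt_fraction_forward: float | None
    alt_fraction_reverse: float | None
    genotype_forward: str | None
    genotype_reverse: str | None
    distance_forward: float | None
    distance_reverse: float | None
    genotype: str
    tier: str  # high_quality | lenient | no_call
    notes: list[str] = field(default_factory=list)

    @property
    def is_variant(self) -> bool:
        return self.genotype in _VARIANT_GENOTYPES and self.tier != "no_call"


@dataclass
class SomaticSNV:
    tumor: GenotypeCall
    normal: GenotypeCall
    somatic: bool
    filter_notes: list[str] = field(default_factory=list)

    @property
    def contig(self) -> str:
        return self.tumor.contig

    @property
    def pos(self) -> int:
        return self.tumor.pos


#: Weights are rounded to multiples of 2**-20 so that sums of many weights
#: are exact in float64 and therefore independent of summation order; the
#: streaming and vectorized call paths then agree bit-for-bit.
_WEIGHT_QUANTUM = 2.0**20


def phred_weight(qual: int) -> float:
    """Probability the base call is correct, ``1 - 10**(-Q/10)``.

    Quantized to 2**-20 to make accumulation order-independent.
    """
    return round((1.0 - 10.0 ** (-qual / 10.0)) * _WEIGHT_QUANTUM) / _WEIGHT_QUANTUM


def weighted_alt_fraction(
    column: PileupColumn, alt: str, strand: str
) -> float | None:
    """Quality-weighted alternate-allele fraction on one strand.

    Returns None (undefined evidence, distinct from fraction 0) when the
    strand has no retained observations.
    """
    obs = column.observations(strand)
    if not obs:
        return None
    total = 0.0
    alt_w = 0.0
    for base, qual in obs:
        w = phred_weight(qual)
        total += w
        if base == alt:
            alt_w += w
    if total == 0.0:
        return None
    return alt_w / total


def ks_distance(observed_fraction: float, genotype: str) -> float:
    """KS sup-distance on two-point support: |p_hat - p_genotype|."""
    return abs(observed_fraction - EXPECTED_ALT_FRACTION[genotype])


def best_genotype(observed_fraction: float) -> tuple[str, float]:
    """Genotype minimizing the KS distance; ties resolved toward the less
    variant genotype (hom_ref < het < hom_alt)."""
    best = min(GENOTYPES, key=lambda g: (ks_distance(observed_fraction, g), GENOTYPES.index(g)))
    return best, ks_distance(observed_fraction, best)


def pick_alt_allele(column: PileupColumn) -> tuple[str | None, list[str]]:
    """Highest-weight non-reference base over both strands.

    Tri-allelic columns evaluate only the top alternate; the remaining
    non-reference bases are returned as notes. Ties break toward the
    alphabetically first base.
    """
    weights: dict[str, float] = {}
    for base, qual in column.observations():
        if base != column.ref_base and base in "ACGT":
            weights[base] = weights.get(base, 0.0) + phred_weight(qual)
    if not weights:
        return None, []
    ranked = sorted(weights, key=lambda b: (-weights[b], b))
    notes = [f"minor_alt:{b}" for b in ranked[1:]]
    return ranked[0], notes


def call_genotype(
    column: PileupColumn,
    thresholds: CallerThresholds = CallerThresholds(),
    mode: str = "standard",
    alt: str | None = None,
) -> GenotypeCall:
    """Call a diploid genotype for one pileup column.

    standard mode: each strand independently selects its minimum-distance
    genotype; the combined call carries tier high_quality only when both
    strands agree, both distances are within the strict threshold, and both
    strands meet the minimum depth. Variant genotypes therefore require both
    strands to provide evidence for the variation.

    variant_consensus mode: strands are pooled; the best variant genotype is
    accepted at tier lenient when its distance is within the lenient
    threshold and each strand holds at least ``min_alt_obs_per_strand``
    alternate observations; otherwise the call falls back to standard mode.
    """
    notes: list[str] = []
    if alt is None:
        alt, notes = pick_alt_allele(column)
    if column.depth == 0:
        return GenotypeCall(
            column.contig, column.pos, column.ref_base, alt,
            None, None, None, None, None, None, "hom_ref", "no_call",
            notes + ["empty_column"],
        )
    if alt is None:
        # no alternate evidence anywhere: hom_ref, tier by depth/strict rule
        alt_f: float | None = 0.0 if column.depth_forward else None
        alt_r: float | None = 0.0 if column.depth_reverse else None
    else:
        alt_f = weighted_alt_fraction(column, alt, "+")
        alt_r = weighted_alt_fraction(column, alt, "-")

    geno_f, dist_f = (None, None) if alt_f is None else best_genotype(alt_f)
    geno_r, dist_r = (None, None) if alt_r is None else best_genotype(alt_r)

    def standard_call() -> tuple[str, str]:
        deep_enough = (
            column.depth_forward >= thresholds.min_depth_per_strand
            and column.depth_reverse >= thresholds.min_depth_per_strand
        )
        if (
            geno_f is not None
            and geno_f == geno_r
            and dist_f <= thresholds.strict_max_distance
            and dist_r <= thresholds.strict_max_distance
            and deep_enough
        ):
            return geno_f, "high_quality"
        # fall-back report: pooled best genotype, but uncallable
        pooled = _pooled_alt_fraction(column, alt)
        geno = best_genotype(pooled)[0] if pooled is not None else "hom_ref"
        return geno, "no_call"

    if mode == "variant_consensus" and alt is not None:
        pooled = _pooled_alt_fraction(column, alt)
        if pooled is not None:
            geno_v = min(
                _VARIANT_GENOTYPES,
                key=lambda g: (ks_distance(pooled, g), GENOTYPES.index(g)),
            )
            alt_obs_f = sum(1 for b, _ in column.forward if b == alt)
            alt_obs_r = sum(1 for b, _ in column.reverse if b == alt)
            if (
                ks_distance(pooled, geno_v) <= thresholds.lenient_max_distance
                and alt_obs_f >= thresholds.min_alt_obs_per_strand
                and alt_obs_r >= thresholds.min_alt_obs_per_strand
            ):
                return GenotypeCall(
                    column.contig, column.pos, column.ref_base, alt,
                    alt_f, alt_r, geno_f, geno_r, dist_f, dist_r,
                    geno_v, "lenient", notes,
                )
    elif mode != "standard" and mode != "variant_consensus":
        raise ValueError(f"unknown mode {mode!r}")

    genotype, tier = standard_call()
    return GenotypeCall(
        column.contig, column.pos, column.ref_base, alt,
        alt_f, alt_r, geno_f, geno_r, dist_f, dist_r, genotype, tier, notes,
    )


def _pooled_alt_fraction(column: PileupColumn, alt: str | None) -> float | None:
    obs = column.observations()
    if not obs:
        return None
    if alt is None:
        return 0.0
    total = sum(phred_weight(q) for _, q in obs)
    alt_w = sum(phred_weight(q) for b, q in obs if b == alt)
    return alt_w / total if total else None


def call_somatic(tumor: GenotypeCall, normal: GenotypeCall) -> SomaticSNV:
    """Somatic iff the tumor call is variant (any tier) and the normal call
    is a high-quality homozygous-reference genotype for the same allele."""
    if (tumor.contig, tumor.pos) != (normal.contig, normal.pos):
        raise PairingError(
            f"locus mismatch: {tumor.contig}:{tumor.pos} vs {normal.contig}:{normal.pos}"
        )
    if tumor.alt is not None and normal.alt is not None and tumor.alt != normal.alt:
        raise PairingError(
            f"{tumor.contig}:{tumor.pos}: allele mismatch {tumor.alt} vs {normal.alt}"
        )
    notes: list[str] = []
    if not tumor.is_variant:
        notes.append("tumor_no_call" if tumor.tier == "no_call" else "tumor_not_variant")
        return SomaticSNV(tumor, normal, False, notes)
    if normal.tier == "high_quality" and normal.genotype == "hom_ref":
        return SomaticSNV(tumor, normal, True, notes)
    if normal.genotype in _VARIANT_GENOTYPES and normal.tier != "no_call":
        notes.append("germline")
    else:
        notes.append("ambiguous_normal")
    return SomaticSNV(tumor, normal, False, notes)


def dual_caller_intersection(
    calls_a: Iterable[GenotypeCall], calls_b: Iterable[GenotypeCall]
) -> tuple[list[GenotypeCall], list[GenotypeCall]]:
    """Compile two call sets: loci called by both configurations.

    Returns ``(intersection, union)`` keyed on (contig, pos, alt); the union
    is retained as the lenient review set. For loci present in both inputs
    the first set's record is kept.
    """
    def key(c: GenotypeCall):
        return (c.contig, c.pos, c.alt)

    a_by_key = {key(c): c for c in calls_a}
    b_by_key = {key(c): c for c in calls_b}
    inter = [a_by_key[k] for k in a_by_key if k in b_by_key]
    union = list(a_by_key.values()) + [b_by_key[k] for k in b_by_key if k not in a_by_key]
    order = lambda c: (c.contig, c.pos)  # noqa: E731
    return sorted(inter, key=order), sorted(union, key=order)
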