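"""End-to-end orchestration: simulate -> pileup -> SNV -> indel -> CNV ->
annotation -> timeline, with a JSON genome summary and a digest manifest.

The summary replaces a circular genome plot with machine-readable per-contig
counts; rerunning with the same configuration and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from . import annotate as ann
from . import cnv as cnvmod
from . import engine, indels, simulate, snv, timeline, vcfio
from .errors import ConfigError
from .resources import longitudinal_matrix_path
from .samio import read_sam

log = logging.getLogger("onb_somatic")

__version__ = "0.1.0"


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulation: simulate.SimulationConfig | None = None
    reference_path: str | None = None
    tumor_sam: str | None = None
    normal_sam: str | None = None
    genes_path: str | None = None
    known_sites_path: str | None = None
    timeline_matrix: str | None = None  # defaults to the packaged matrix
    thresholds: snv.CallerThresholds = field(default_factory=snv.CallerThresholds)
    insert_interval: tuple[int, int] = indels.DEFAULT_INSERT_INTERVAL
    indel_min_support: int = 2
    cnv_window_size: int = cnvmod.DEFAULT_WINDOW_SIZE
    cnv_gain_threshold: float = 0.3
    cnv_loss_threshold: float = -0.3
    cnv_min_windows: int = 3

    def validate(self) -> None:
        if self.simulation is None:
            for name in ("reference_path", "tumor_sam", "normal_sam"):
                path = getattr(self, name)
                if path is None or not os.path.exists(path):
                    raise ConfigError(f"{name} missing or does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim = raw.pop("simulation", None)
        thresholds = raw.pop("thresholds", None)
        config = cls(**{**raw})
        if sim is not None:
            if "contig_lengths" in sim:
                sim["contig_lengths"] = tuple(sim["contig_lengths"])
            if "cnv_segments" in sim:
                sim["cnv_segments"] = tuple(tuple(s) for s in sim["cnv_segments"])
            if "indel_size_range" in sim:
                sim["indel_size_range"] = tuple(sim["indel_size_range"])
            sim.setdefault("seed", config.seed)
            config.simulation = simulate.SimulationConfig(**sim)
        if thresholds is not None:
            config.thresholds = snv.CallerThresholds(**thresholds)
        if isinstance(config.insert_interval, list):
            config.insert_interval = tuple(config.insert_interval)
        return config

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class GenomeSummary:
    per_contig: dict
    variant_stats: dict
    gained_genes: list[str]
    lost_genes: list[str]
    timeline: dict
    n_somatic_snvs: int
    n_somatic_indels: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def blocks_from_sam(path: str) -> dict[str, engine.ReadBlock]:
    """Group a SAM file's mapped reads into per-contig ReadBlocks."""
    by_contig: dict[str, list] = {}
    for read in read_sam(path):
        if read.mapped:
            by_contig.setdefault(read.contig, []).append(read)
    return {
        contig: engine.ReadBlock.from_reads(contig, reads)
        for contig, reads in by_contig.items()
    }


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def snv_stage(
    tumor_blocks: Mapping[str, engine.ReadBlock],
    normal_blocks: Mapping[str, engine.ReadBlock],
    reference: Mapping[str, str],
    thresholds: snv.CallerThresholds,
) -> tuple[list[snv.SomaticSNV], list[snv.GenotypeCall], list[snv.GenotypeCall]]:
    """Somatic SNV calling over aggregate pileups.

    Returns (somatic_snvs, compiled_tumor_calls, germline_calls): the tumor
    is called in Variant Consensus mode and in standard mode, the two call
    sets are compiled by intersection (the union is kept in the review set
    attached to each call's notes), the matched normal is genotyped in
    standard mode at every tumor-variant locus, and the germline call list
    holds the normal's own high-quality variant genotypes.
    """
    somatic: list[snv.SomaticSNV] = []
    compiled: list[snv.GenotypeCall] = []
    germline: list[snv.GenotypeCall] = []
    for contig, tumor_block in sorted(tumor_blocks.items()):
        if contig not in normal_blocks:
            continue
        length = len(reference[contig])
        ref_codes = engine.encode_bases(reference[contig]).astype(np.int64)
        t_counts, t_wsum = engine.strand_base_aggregates(tumor_block, length)
        n_counts, n_wsum = engine.strand_base_aggregates(normal_blocks[contig], length)

        consensus_variants: list[snv.GenotypeCall] = []
        standard_variants: list[snv.GenotypeCall] = []
        for p0 in engine.candidate_positions(t_counts, ref_codes):
            ref_base = reference[contig][p0]
            cons = engine.call_at_position(
                contig, p0, ref_base, t_counts, t_wsum, thresholds, "variant_consensus"
            )
            std = engine.call_at_position(
                contig, p0, ref_base, t_counts, t_wsum, thresholds, "standard", alt=cons.alt
            )
            if cons.is_variant:
                consensus_variants.append(cons)
            if std.is_variant:
                standard_variants.append(std)
            tumor_call = cons if cons.is_variant else std
            if not tumor_call.is_variant:
                continue
            normal_call = engine.call_at_position(
                contig, p0, ref_base, n_counts, n_wsum, thresholds, "standard",
                alt=tumor_call.alt,
            )
            somatic.append(snv.call_somatic(tumor_call, normal_call))
        inter, union = snv.dual_caller_intersection(standard_variants, consensus_variants)
        compiled.extend(inter)

        for p0 in engine.candidate_positions(n_counts, ref_codes):
            ref_base = reference[contig][p0]
            call = engine.call_at_position(
                contig, p0, ref_base, n_counts, n_wsum, thresholds, "standard"
            )
            if call.is_variant and call.tier == "high_quality":
                germline.append(call)
    return somatic, compiled, germline


def indel_stage(
    tumor_blocks: Mapping[str, engine.ReadBlock],
    normal_blocks: Mapping[str, engine.ReadBlock],
    reference: Mapping[str, str],
    interval: tuple[int, int],
    min_support: int,
) -> list[indels.SomaticIndel]:
    calls = []
    for contig in sorted(tumor_blocks):
        if contig not in normal_blocks:
            continue
        calls.extend(
            indels.call_somatic_indels(
                tumor_blocks[contig], normal_blocks[contig], reference,
                interval=interval, min_support=min_support,
            )
        )
    return calls


def cnv_stage(
    tumor_blocks: Mapping[str, engine.ReadBlock],
    normal_blocks: Mapping[str, engine.ReadBlock],
    contig_lengths: Mapping[str, int],
    window_size: int,
    gain_threshold: float,
    loss_threshold: float,
    min_windows: int,
) -> tuple[list[cnvmod.CopyNumberSegment], dict, dict]:
    tumor_clones = {}
    normal_clones = {}
    for contig in sorted(tumor_blocks):
        if contig not in normal_blocks:
            continue
        ts, te, _ = cnvmod.extract_clones(tumor_blocks[contig])
        ns, ne, _ = cnvmod.extract_clones(normal_blocks[contig])
        tumor_clones[contig] = (ts, te)
        normal_clones[contig] = (ns, ne)
    tumor_tracks = cnvmod.build_coverage_tracks(tumor_clones, contig_lengths, window_size)
    normal_tracks = cnvmod.build_coverage_tracks(normal_clones, contig_lengths, window_size)
    segments = []
    for contig in sorted(tumor_tracks):
        ratios = cnvmod.log2_relative(tumor_tracks[contig], normal_tracks[contig])
        segments.extend(
            cnvmod.segment_and_call(
                ratios, contig, contig_lengths[contig], window_size,
                gain_threshold, loss_threshold, min_windows,
            )
        )
    return segments, tumor_tracks, normal_tracks


def timeline_stage(matrix_path: str | None) -> dict:
    matrix = timeline.load_presence_matrix(matrix_path or longitudinal_matrix_path())
    return timeline.acquisition_report(timeline.classify_acquisition(matrix))


# ----------------------------------------------------------------------
# run_all
# ----------------------------------------------------------------------

def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> GenomeSummary:
    """Execute every stage under ``config.outdir`` and return the summary.

    Outputs: somatic SNV and indel VCFs, CNV segment BED, gene gain/loss
    TSV, consequence TSV, summary.json and manifest.json (sha256 digests of
    every written file plus the resolved configuration).
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    outputs: list[str] = []

    def outpath(name: str) -> str:
        path = os.path.join(config.outdir, name)
        outputs.append(path)
        return path

    # --- stage: inputs ----------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        log.info("stage simulate: %d contigs", len(sim.contig_lengths))
        reference, truth = simulate.simulate_reference(sim)
        tumor_blocks = simulate.simulate_read_pairs(reference, truth, sim, "tumor")
        normal_blocks = simulate.simulate_read_pairs(reference, truth, sim, "normal")
        contig_lengths = dict(zip(sim.contig_names(), sim.contig_lengths))
        vcfio.write_fasta(outpath("reference.fa"), reference)
        vcfio.write_sites_vcf(
            outpath("truth_germline.vcf"),
            [(c, p, r, a) for c, p, r, a, _ in truth.germline_snps],
            contig_lengths,
        )
        vcfio.write_sites_vcf(
            outpath("truth_somatic_snvs.vcf"),
            [(c, p, r, a) for c, p, r, a, _ in truth.somatic_snvs],
            contig_lengths,
        )
        vcfio.write_bed(
            outpath("truth_cnv.bed"),
            [(c, s, e, f"cn{cn}") for c, s, e, cn in truth.cnv_segments],
        )
        vcfio.write_sites_vcf(outpath("known_sites.vcf"), truth.known_sites, contig_lengths)
        ann.write_gene_models(outpath("genes.tsv"), truth.genes)
        genes = truth.genes
        known_sites = truth.known_sites
    else:
        log.info("stage load: %s", config.reference_path)
        reference = vcfio.read_fasta(config.reference_path)
        contig_lengths = {c: len(s) for c, s in reference.items()}
        tumor_blocks = blocks_from_sam(config.tumor_sam)
        normal_blocks = blocks_from_sam(config.normal_sam)
        genes = ann.read_gene_models(config.genes_path) if config.genes_path else []
        known_sites = (
            vcfio.read_sites_vcf(config.known_sites_path)
            if config.known_sites_path
            else set()
        )

    # --- stage: duplicate flagging ---------------------------------------
    for block in (*tumor_blocks.values(), *normal_blocks.values()):
        block.flag_duplicates()
    log.info(
        "stage duplicates: tumor %d reads, normal %d reads",
        sum(len(b) for b in tumor_blocks.values()),
        sum(len(b) for b in normal_blocks.values()),
    )

    # --- stage: SNV -------------------------------------------------------
    somatic_snvs, compiled, germline_calls = snv_stage(
        tumor_blocks, normal_blocks, reference, config.thresholds
    )
    somatic_only = [s for s in somatic_snvs if s.somatic]
    vcfio.write_somatic_snv_vcf(outpath("somatic_snvs.vcf"), somatic_snvs, contig_lengths)
    log.info(
        "stage snv: %d tumor-variant loci, %d somatic, %d germline calls",
        len(somatic_snvs), len(somatic_only), len(germline_calls),
    )

    # --- stage: indel -----------------------------------------------------
    somatic_indels = indel_stage(
        tumor_blocks, normal_blocks, reference,
        config.insert_interval, config.indel_min_support,
    )
    somatic_indels_only = [c for c in somatic_indels if c.somatic]
    vcfio.write_somatic_indel_vcf(
        outpath("somatic_indels.vcf"), somatic_indels, reference, contig_lengths
    )
    log.info(
        "stage indel: %d candidates, %d somatic",
        len(somatic_indels), len(somatic_indels_only),
    )

    # --- stage: CNV -------------------------------------------------------
    segments, tumor_tracks, normal_tracks = cnv_stage(
        tumor_blocks, normal_blocks, contig_lengths,
        config.cnv_window_size, config.cnv_gain_threshold,
        config.cnv_loss_threshold, config.cnv_min_windows,
    )
    called = [s for s in segments if s.call != cnvmod.NEUTRAL]
    vcfio.write_bed(
        outpath("cnv_segments.bed"),
        [(s.contig, s.start, s.end, f"{s.call}:{s.log2_ratio:.3f}") for s in called],
    )
    vcfio.write_bedgraph(
        outpath("tumor_coverage.bedgraph"),
        [tumor_tracks[c] for c in sorted(tumor_tracks)],
    )
    gained, lost = cnvmod.genes_in_segments(segments, genes) if genes else ([], [])
    with open(outpath("gene_copy_calls.tsv"), "w") as handle:
        handle.write("gene\tcall\n")
        for name in gained:
            handle.write(f"{name}\tgain\n")
        for name in lost:
            handle.write(f"{name}\tloss\n")
    log.info("stage cnv: %d non-neutral segments, %d gained / %d lost genes",
             len(called), len(gained), len(lost))

    # --- stage: annotation ------------------------------------------------
    consequences = []
    for call in somatic_only:
        cons = ann.annotate_snv(
            genes, reference, call.contig, call.pos, call.tumor.alt
        )
        if cons is not None:
            consequences.append(cons)
    indel_effects = []
    for call in somatic_indels_only:
        for model in genes:
            effect = ann.classify_indel_consequence(model, call.candidate)
            if effect != ann.EFFECT_NON_CODING:
                indel_effects.append((call.candidate, model.name, effect))
    with open(outpath("coding_consequences.tsv"), "w") as handle:
        handle.write(
            "gene\tpos\tcodon_index\tref_codon\tmut_codon\tref_aa\tmut_aa\teffect\n"
        )
        for c in consequences:
            handle.write(
                f"{c.gene}\t{c.pos}\t{c.codon_index}\t{c.ref_codon}\t{c.mut_codon}"
                f"\t{c.ref_aa}\t{c.mut_aa}\t{c.effect}\n"
            )
        for cand, gene_name, effect in indel_effects:
            handle.write(
                f"{gene_name}\t{cand.start}\t.\t.\t{cand.kind}:{cand.sequence}\t.\t.\t{effect}\n"
            )
    germline_sites = [
        (c.contig, c.pos, c.ref, c.alt) for c in germline_calls if c.alt is not None
    ]
    stats = ann.summary_stats(germline_sites, known_sites)
    log.info(
        "stage annotate: %d coding consequences; germline Ti/Tv %.2f, known fraction %.3f",
        len(consequences),
        stats.titv_ratio if stats.titv_ratio is not None else float("nan"),
        stats.known_fraction,
    )

    # --- stage: timeline --------------------------------------------------
    timeline_report = timeline_stage(config.timeline_matrix)

    # --- summary + manifest ----------------------------------------------
    per_contig = {}
    for contig in sorted(contig_lengths):
        per_contig[contig] = {
            "somatic_snvs": sum(1 for s in somatic_only if s.contig == contig),
            "somatic_indels": sum(
                1 for c in somatic_indels_only if c.candidate.contig == contig
            ),
            "gain_segments": sum(
                1 for s in called if s.contig == contig and s.call == cnvmod.GAIN
            ),
            "loss_segments": sum(
                1 for s in called if s.contig == contig and s.call == cnvmod.LOSS
            ),
        }
    summary = GenomeSummary(
        per_contig=per_contig,
        variant_stats={
            "n_germline_snvs": stats.n_snvs,
            "n_transitions": stats.n_transitions,
            "n_transversions": stats.n_transversions,
            "titv_ratio": stats.titv_ratio,
            "known_fraction": stats.known_fraction,
        },
        gained_genes=gained,
        lost_genes=lost,
        timeline=timeline_report,
        n_somatic_snvs=len(somatic_only),
        n_somatic_indels=len(somatic_indels_only),
    )
    assert sum(v["somatic_snvs"] for v in per_contig.values()) == summary.n_somatic_snvs
    assert (
        sum(v["somatic_indels"] for v in per_contig.values()) == summary.n_somatic_indels
    )
    with open(outpath("summary.json"), "w") as handle:
        json.dump(summary.to_dict(), handle, indent=2, sort_keys=True)

    manifest = {
        "version": __version__,
        "config": _jsonable(config.to_dict()),
        "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
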