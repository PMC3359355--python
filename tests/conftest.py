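import numpy as np
import pytest

from onb_somatic.pileup import PileupColumn
from onb_somatic.samio import AlignedRead
from onb_somatic.simulate import SimulationConfig, simulate_read_pairs, simulate_reference


def make_read(
    contig="chr1",
    pos=1,
    bases="A" * 100,
    quals=None,
    name="r1",
    is_reverse=False,
    cigar=None,
    mate_pos=None,
    tlen=0,
    flags=0x1,
):
    quals = quals if quals is not None else [30] * len(bases)
    cigar = cigar or [("M", len(bases))]
    return AlignedRead(
        name=name,
        contig=contig,
        pos=pos,
        is_reverse=is_reverse,
        mapped=True,
        cigar=cigar,
        bases=bases,
        quals=quals,
        mate_contig=contig,
        mate_pos=mate_pos,
        tlen=tlen,
        flags=flags,
    )


def make_column(ref="A", forward=(), reverse=(), contig="chr1", pos=100):
    """forward/reverse: iterables of (base, quality)."""
    return PileupColumn(contig, pos, ref, list(forward), list(reverse))


@pytest.fixture(scope="session")
def small_sim():
    """A 100 kb tumor/normal simulation shared across tests."""
    config = SimulationConfig(
        seed=7,
        contig_lengths=(100_000,),
        n_somatic_snvs=25,
        somatic_vaf=0.5,
        n_somatic_indels=5,
        n_germline_indels=5,
        depth_tumor=60,
        depth_normal=30,
        n_genes=12,
    )
    reference, truth = simulate_reference(config)
    tumor = simulate_read_pairs(reference, truth, config, "tumor")
    normal = simulate_read_pairs(reference, truth, config, "normal")
    for block in (*tumor.values(), *normal.values()):
        block.flag_duplicates()
    return config, reference, truth, tumor, normal
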