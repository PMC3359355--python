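import numpy as np
import pytest

from onb_somatic.indels import (
    DELETION,
    INSERTION,
    IndelCandidate,
    call_somatic_indels,
    discover_candidates,
    filter_by_insert,
    left_normalize,
    read_indel_tsv,
    somatic_test,
    write_indel_tsv,
)
from onb_somatic.resources import validated_indel_records

from conftest import make_read


def oracle_left_shift(ref, cand):
    """Independent normalization oracle: shift left one base at a time while
    the edited haplotype stays identical."""

    def haplotype(c):
        if c.kind == DELETION:
            return ref[: c.start - 1] + ref[c.end :]
        return ref[: c.start] + c.sequence + ref[c.start :]

    target = haplotype(cand)
    best = cand
    while True:
        if best.kind == DELETION:
            if best.start <= 1:
                break
            shifted = IndelCandidate(
                best.contig, best.start - 1, best.end - 1, DELETION,
                ref[best.start - 2 : best.end - 1],
            )
        else:
            if best.start <= 1:
                break
            shifted = IndelCandidate(
                best.contig, best.start - 1, best.start - 1, INSERTION,
                ref[best.start - 1] + best.sequence[:-1],
            )
        if haplotype(shifted) != target:
            break
        best = shifted
    return best


class TestIndelCandidate:
    def test_deletion_span_must_match_sequence(self):
        with pytest.raises(ValueError):
            IndelCandidate("chr1", 10, 12, DELETION, "AT")

    def test_insertion_anchor_invariant(self):
        with pytest.raises(ValueError):
            IndelCandidate("chr1", 10, 11, INSERTION, "AT")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            IndelCandidate("chr1", 10, 10, INSERTION, "")


class TestLeftNormalize:
    def test_deletion_in_homopolymer_shifts_to_run_start(self):
        #        123456789
        ref = "GGAAAATCGG"
        cand = IndelCandidate("chr1", 6, 6, DELETION, "A")
        norm = left_normalize(ref, cand)
        assert norm.start == 3
        assert norm.sequence == "A"

    def test_insertion_rotates_through_repeat(self):
        ref = "GGCACACATT"
        cand = IndelCandidate("chr1", 8, 8, INSERTION, "CA")
        norm = left_normalize(ref, cand)
        assert norm.start < 8

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_shift_until_mismatch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # low-complexity sequence to provoke plenty of shifting
        ref = "".join(rng.choice(list("AACG")) for _ in range(200))
        for _ in range(30):
            start = int(rng.integers(20, 180))
            size = int(rng.integers(1, 8))
            if rng.random() < 0.5:
                cand = IndelCandidate(
                    "chr1", start, start + size - 1, DELETION,
                    ref[start - 1 : start + size - 1],
                )
            else:
                ins = "".join(rng.choice(list("ACGT")) for _ in range(size))
                cand = IndelCandidate("chr1", start, start, INSERTION, ins)
            assert left_normalize(ref, cand) == oracle_left_shift(ref, cand)


class TestFilterByInsert:
    @pytest.mark.parametrize(
        "tlen,kept", [(300, True), (500, False), (-500, False), (49, False), (51, True), (50, False)]
    )
    def test_open_interval_bounds(self, tlen, kept):
        read = make_read(tlen=tlen, mate_pos=500)
        assert bool(filter_by_insert([read])) is kept

    def test_reads_without_mate_removed(self):
        read = make_read(tlen=300, mate_pos=None)
        assert filter_by_insert([read]) == []


def _gapped_reads(n, pos, cigar, contig="chr1", bases=None):
    return [
        make_read(
            name=f"g{i}", pos=pos, cigar=cigar,
            bases=bases or "A" * sum(l for op, l in cigar if op in "MI"),
            tlen=300, mate_pos=pos + 200,
        )
        for i in range(n)
    ]


REF = {"chr1": "ACGT" * 2500}


class TestDiscoverCandidates:
    def test_support_counted_and_aggregated(self):
        reads = _gapped_reads(6, 101, [("M", 50), ("D", 2), ("M", 50)])
        cands = discover_candidates(reads, REF, min_support=2)
        assert len(cands) == 1
        assert cands[0].supporting_reads == 6
        assert cands[0].kind == DELETION
        assert len(cands[0].sequence) == 2

    def test_single_read_below_min_support(self):
        reads = _gapped_reads(1, 101, [("M", 50), ("D", 2), ("M", 50)])
        assert discover_candidates(reads, REF, min_support=2) == []

    def test_candidates_are_left_normalized(self):
        ref = {"chr1": "G" * 50 + "AAAA" + "T" * 146}
        # delete the 3rd A of the AAAA run (positions 51-54)
        reads = _gapped_reads(3, 31, [("M", 22), ("D", 1), ("M", 78)])
        cands = discover_candidates(reads, ref, min_support=2)
        assert len(cands) == 1
        assert cands[0].start == 51  # leftmost placement in the run


class TestSomaticTest:
    def _normal_clean(self, pos=50):
        return [make_read(name=f"n{i}", pos=pos, tlen=300, mate_pos=pos + 200) for i in range(12)]

    def test_normal_with_matching_deletion_vetoes(self):
        cand = IndelCandidate("chr1", 151, 152, DELETION, REF["chr1"][150:152])
        normal = self._normal_clean() + _gapped_reads(
            2, 101, [("M", 50), ("D", 2), ("M", 50)]
        )
        result = somatic_test(cand, normal, REF)
        assert not result.somatic
        assert result.normal_indel_evidence > 0

    def test_clean_normal_window_is_somatic(self):
        cand = IndelCandidate("chr1", 151, 152, DELETION, REF["chr1"][150:152])
        result = somatic_test(cand, self._normal_clean(), REF)
        assert result.somatic

    def test_normal_indel_just_outside_window_ignored(self):
        # candidate at 151; a normal deletion ending at 145 = start-6 is outside
        cand = IndelCandidate("chr1", 151, 151, DELETION, REF["chr1"][150])
        outside = _gapped_reads(2, 101, [("M", 44), ("D", 1), ("M", 56)])
        for ev in outside:
            assert ev.cigar[0][1] == 44  # deletion at ref position 145
        result = somatic_test(cand, self._normal_clean() + outside, REF)
        assert result.somatic

    def test_normal_indel_on_window_boundary_counts(self):
        # deletion at 146 = start-5 is the inclusive boundary
        cand = IndelCandidate("chr1", 151, 151, DELETION, REF["chr1"][150])
        boundary = _gapped_reads(2, 101, [("M", 45), ("D", 1), ("M", 55)])
        result = somatic_test(cand, self._normal_clean() + boundary, REF)
        assert not result.somatic

    def test_no_normal_coverage_is_conservatively_non_somatic(self):
        cand = IndelCandidate("chr1", 5001, 5001, DELETION, REF["chr1"][5000])
        result = somatic_test(cand, self._normal_clean(pos=50), REF)
        assert not result.somatic
        assert "no_normal_coverage" in result.notes


class TestEndToEnd:
    def test_somatic_indels_recovered_and_germline_rejected(self, small_sim):
        config, reference, truth, tumor, normal = small_sim
        contig = config.contig_names()[0]
        calls = call_somatic_indels(tumor[contig], normal[contig], reference)
        called = {
            (c.candidate.start, c.candidate.kind, c.candidate.sequence)
            for c in calls
            if c.somatic
        }
        truth_somatic = {
            (c.start, c.kind, c.sequence) for c in truth.somatic_indels
        }
        recovered = len(called & truth_somatic) / len(truth_somatic)
        assert recovered >= 0.9
        # no truth germline indel may be called somatic
        germline = {(c.start, c.kind, c.sequence) for c, _ in truth.germline_indels}
        assert not called & germline


class TestFixtureRoundTrip:
    def test_validated_indel_records_roundtrip(self, tmp_path):
        records = validated_indel_records()
        assert len(records) == 5
        kinds = [r.kind for r in records]
        assert kinds.count(DELETION) == 3 and kinds.count(INSERTION) == 2
        path = tmp_path / "indels.tsv"
        write_indel_tsv(str(path), records)
        back = read_indel_tsv(str(path))
        assert back == records
        assert [len(r.sequence) for r in back] == [1, 7, 1, 1, 7]
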