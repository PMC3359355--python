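import numpy as np
import pytest

from onb_somatic import cnv
from onb_somatic.annotate import GeneModel
from onb_somatic.errors import ConfigError

from conftest import make_read


def _pair_reads(pos, tlen, name):
    return [
        make_read(name=name, pos=pos, tlen=tlen, mate_pos=pos + tlen - 100),
        make_read(
            name=name, pos=pos + tlen - 100, tlen=-tlen, mate_pos=pos,
            is_reverse=True,
        ),
    ]


class TestExtractClones:
    def test_clone_spans_both_mates_and_gap(self):
        reads = []
        for i in range(120):
            reads += _pair_reads(1001, 300, f"p{i}")
        starts, ends, stats = cnv.extract_clones(reads)
        assert starts[0] == 1001
        assert ends[0] == 1300

    def test_outlier_insert_excluded_beyond_two_sd(self):
        rng = np.random.default_rng(1)
        reads = []
        tlens = np.rint(rng.normal(300, 10, 300)).astype(int)
        for i, t in enumerate(tlens):
            reads += _pair_reads(1000 + i, int(t), f"p{i}")
        reads += _pair_reads(5000, 300 + 80, "outlier")  # mean + 8 sd
        starts, ends, (mean, sd) = cnv.extract_clones(reads)
        assert 5000 not in starts.tolist()
        assert len(starts) <= 301

    def test_unmapped_mate_excluded(self):
        reads = []
        for i in range(120):
            reads += _pair_reads(1000 + i, 300, f"p{i}")
        solo = make_read(name="solo", pos=2000, tlen=0, mate_pos=None)
        starts, _, _ = cnv.extract_clones(reads + [solo])
        assert 2000 not in starts.tolist()

    def test_too_few_pairs_refused(self):
        reads = _pair_reads(1000, 300, "only")
        with pytest.raises(ConfigError, match="proper pairs"):
            cnv.extract_clones(reads)


class TestCloneDepth:
    def test_matches_bruteforce_interval_stabbing(self):
        rng = np.random.default_rng(2)
        starts = rng.integers(1, 4000, 100)
        ends = starts + rng.integers(100, 500, 100)
        depth = cnv.clone_depth(starts, ends, 5000)
        for pos in rng.integers(1, 5001, 50):
            expected = int(np.sum((starts <= pos) & (ends >= pos)))
            assert depth[pos - 1] == expected

    def test_hand_built_three_clone_toy(self):
        # windows [1,2000] and [2001,4000]
        starts = np.array([1, 1001, 3001])
        ends = np.array([2000, 3000, 4000])
        track = cnv.coverage_track(starts, ends, "chr1", 4000, window_size=2000)
        # brute force per-base averages
        depth = np.zeros(4000)
        for s, e in zip(starts, ends):
            depth[s - 1 : e] += 1
        assert track.window_means[0] == pytest.approx(depth[:2000].mean())
        assert track.window_means[1] == pytest.approx(depth[2000:].mean())


class TestCoverageTrack:
    def test_identical_clones_fill_window(self):
        starts = np.repeat(1, 10)
        ends = np.repeat(2000, 10)
        track = cnv.coverage_track(starts, ends, "chr1", 2000, window_size=2000)
        assert track.window_means[0] == 10

    def test_uniform_depth_normalizes_to_one(self):
        starts = np.arange(1, 20001, 2)  # heavy uniform tiling
        ends = starts + 399
        track = cnv.coverage_track(starts, ends, "chr1", 20_000)
        inner = track.normalized[2:-2]
        assert np.allclose(inner, 1.0, atol=0.05)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ConfigError):
            cnv.coverage_track(np.array([1]), np.array([100]), "chr1", 1000, window_size=0)

    def test_normalization_invariant_under_global_scaling(self):
        rng = np.random.default_rng(3)
        starts = np.sort(rng.integers(1, 48_000, 3000))
        ends = starts + 325
        base = cnv.coverage_track(starts, ends, "chr1", 50_000)
        for factor in (0.5, 2):
            n = int(len(starts) * factor)
            if factor > 1:
                scaled_starts = np.sort(np.concatenate([starts, starts]))[:n]
                scaled_ends = scaled_starts + 325
            else:
                idx = np.sort(rng.permutation(len(starts))[:n])
                scaled_starts, scaled_ends = starts[idx], ends[idx]
            scaled = cnv.coverage_track(scaled_starts, scaled_ends, "chr1", 50_000)
            inner = slice(2, -2)
            assert np.allclose(
                scaled.normalized[inner], base.normalized[inner], atol=0.25
            )


class TestLog2Relative:
    def _track(self, normalized):
        n = len(normalized)
        return cnv.CloneCoverageTrack(
            "chr1", 2000, np.arange(1, 2000 * n, 2000), np.asarray(normalized) * 30.0,
            30.0, np.asarray(normalized, dtype=float),
        )

    def test_equal_tracks_give_zero(self):
        r = cnv.log2_relative(self._track([1, 1, 1]), self._track([1, 1, 1]), pseudocount=0)
        assert np.allclose(r, 0.0)

    def test_doubled_tumor_gives_one(self):
        r = cnv.log2_relative(self._track([2, 2]), self._track([1, 1]), pseudocount=0)
        assert np.allclose(r, 1.0)

    def test_low_normal_masked(self):
        r = cnv.log2_relative(self._track([1, 1]), self._track([1, 0.01]))
        assert np.isnan(r[1])

    def test_tiling_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            cnv.log2_relative(self._track([1, 1]), self._track([1, 1, 1]))


class TestSegmentation:
    def test_all_zero_is_single_neutral_segment(self):
        segs = cnv.segment_and_call(np.zeros(10), "chr1", 20_000)
        assert len(segs) == 1
        assert segs[0].call == "neutral"
        assert (segs[0].start, segs[0].end) == (1, 20_000)

    def test_long_gain_run_merged(self):
        ratios = np.concatenate([np.zeros(5), np.full(10, 1.0), np.zeros(5)])
        segs = cnv.segment_and_call(ratios, "chr1", 40_000, min_windows=3)
        gains = [s for s in segs if s.call == "gain"]
        assert len(gains) == 1
        assert gains[0].n_windows == 10

    def test_alternating_single_windows_all_neutral(self):
        ratios = np.array([1.0, -1.0] * 5)
        segs = cnv.segment_and_call(ratios, "chr1", 20_000, min_windows=3)
        assert all(s.call == "neutral" for s in segs)

    def test_runs_match_runlength_oracle(self):
        rng = np.random.default_rng(4)
        ratios = rng.choice([0.0, 1.0, -1.0], size=60)
        segs = cnv.segment_and_call(ratios, "chr1", 120_000, min_windows=3)
        # oracle: windows belong to a non-neutral call iff inside a run >= 3
        state = np.array(["neutral"] * 60, dtype=object)
        i = 0
        while i < 60:
            j = i
            while j < 60 and ratios[j] == ratios[i]:
                j += 1
            if j - i >= 3 and ratios[i] != 0.0:
                state[i:j] = "gain" if ratios[i] > 0 else "loss"
            i = j
        rebuilt = np.empty(60, dtype=object)
        for s in segs:
            w0 = (s.start - 1) // 2000
            rebuilt[w0 : w0 + s.n_windows] = s.call
        assert np.array_equal(rebuilt, state)


class TestGenesInSegments:
    SEGS = [
        cnv.CopyNumberSegment("chr1", 10_001, 30_000, 1.0, "gain", 10),
        cnv.CopyNumberSegment("chr1", 50_001, 70_000, -1.0, "loss", 10),
    ]

    def _gene(self, name, start, end):
        return GeneModel(name, "chr1", "+", ((start, end),))

    def test_gene_inside_loss_segment_reported_lost(self):
        gained, lost = cnv.genes_in_segments(self.SEGS, [self._gene("G", 55_000, 60_000)])
        assert lost == ["G"] and gained == []

    def test_gene_without_overlap_in_neither_list(self):
        gained, lost = cnv.genes_in_segments(self.SEGS, [self._gene("G", 80_000, 90_000)])
        assert gained == [] and lost == []

    def test_forty_percent_overlap_below_half_rule(self):
        # gene 25001-50000 (25 kb): 5 kb inside the gain segment = 20%
        gained, lost = cnv.genes_in_segments(self.SEGS, [self._gene("G", 25_001, 50_000)])
        assert gained == []
        # but a 10 kb gene with 6 kb inside (60%) qualifies
        gained, _ = cnv.genes_in_segments(self.SEGS, [self._gene("G", 24_001, 34_000)])
        assert gained == ["G"]

    def test_unmatched_contig_rejected(self):
        other = GeneModel("G", "chrX", "+", ((1, 100),))
        with pytest.raises(ConfigError, match="chrX"):
            cnv.genes_in_segments(self.SEGS, [other])


class TestCnvRecoverySmall:
    def test_spiked_gain_and_loss_recovered(self):
        from onb_somatic.simulate import SimulationConfig, simulate_read_pairs, simulate_reference
        from onb_somatic import pipeline

        config = SimulationConfig(
            seed=11,
            contig_lengths=(400_000,),
            germline_snp_rate=1e-4,
            n_somatic_snvs=0,
            n_somatic_indels=0,
            n_germline_indels=0,
            cnv_segments=(("chr1", 100_001, 160_000, 4), ("chr1", 250_001, 310_000, 1)),
            depth_tumor=30,
            depth_normal=30,
            n_genes=0,
        )
        reference, truth = simulate_reference(config)
        tumor = simulate_read_pairs(reference, truth, config, "tumor")
        normal = simulate_read_pairs(reference, truth, config, "normal")
        for b in (*tumor.values(), *normal.values()):
            b.flag_duplicates()
        segments, _, _ = pipeline.cnv_stage(
            tumor, normal, {"chr1": 400_000}, 2000, 0.3, -0.3, 3
        )
        gains = [s for s in segments if s.call == "gain"]
        losses = [s for s in segments if s.call == "loss"]
        assert len(gains) == 1 and len(losses) == 1
        assert gains[0].log2_ratio == pytest.approx(1.0, abs=0.3)
        assert losses[0].log2_ratio == pytest.approx(-1.0, abs=0.3)
        for seg, (t_start, t_end) in ((gains[0], (100_001, 160_000)), (losses[0], (250_001, 310_000))):
            assert abs(seg.start - t_start) <= 2 * 2000
            assert abs(seg.end - t_end) <= 2 * 2000
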