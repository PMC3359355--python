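import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onb_somatic.snv import (
    EXPECTED_ALT_FRACTION,
    GENOTYPES,
    CallerThresholds,
    best_genotype,
    call_genotype,
    call_somatic,
    dual_caller_intersection,
    ks_distance,
    phred_weight,
    weighted_alt_fraction,
)
from onb_somatic.errors import PairingError

from conftest import make_column


def oracle_genotype_per_strand(observations, alt):
    """Independent brute-force minimizer: explicit weighted empirical CDF on
    the two-point support {ref=0, alt=1} compared against each genotype's
    expected CDF; exhaustive search over the three genotypes."""
    total = sum(phred_weight(q) for _, q in observations)
    p_alt = sum(phred_weight(q) for b, q in observations if b == alt) / total
    best, best_d = None, None
    for g in GENOTYPES:  # order encodes the tie-break (less variant wins)
        e = EXPECTED_ALT_FRACTION[g]
        # sup over support points x in {0, 1} of |F_emp(x) - F_g(x)|
        d = max(abs((1 - p_alt) - (1 - e)), abs(1.0 - 1.0))
        if best_d is None or d < best_d:
            best, best_d = g, d
    return best, best_d


class TestWeightedAltFraction:
    def test_all_alt_is_one(self):
        col = make_column(ref="A", forward=[("C", 30)] * 10)
        assert weighted_alt_fraction(col, "C", "+") == 1.0

    def test_equal_mix_is_half(self):
        col = make_column(ref="A", forward=[("A", 25)] * 5 + [("C", 25)] * 5)
        assert weighted_alt_fraction(col, "C", "+") == pytest.approx(0.5)

    def test_hand_computed_weighting(self):
        # 1 alt at Q10 (w=0.9) vs 1 ref at Q30 (w=0.999): 0.9/1.899
        col = make_column(ref="A", forward=[("C", 10), ("A", 30)])
        frac = weighted_alt_fraction(col, "C", "+")
        assert frac == pytest.approx(0.9 / 1.899, abs=1e-4)

    def test_empty_strand_is_undefined_not_zero(self):
        col = make_column(ref="A", forward=[("C", 30)])
        assert weighted_alt_fraction(col, "C", "-") is None

    def test_equal_qualities_reduce_to_unweighted_fraction(self):
        for n_alt in range(0, 8):
            obs = [("C", 33)] * n_alt + [("A", 33)] * (8 - n_alt)
            col = make_column(ref="A", forward=obs)
            assert weighted_alt_fraction(col, "C", "+") == pytest.approx(n_alt / 8)

    @given(
        alts=st.integers(0, 10),
        refs=st.integers(1, 10),
        q_new=st.integers(2, 40),
    )
    @settings(deadline=None, max_examples=60)
    def test_adding_alt_never_decreases_fraction(self, alts, refs, q_new):
        obs = [("C", 30)] * alts + [("A", 28)] * refs
        col = make_column(ref="A", forward=obs)
        before = weighted_alt_fraction(col, "C", "+")
        col2 = make_column(ref="A", forward=obs + [("C", q_new)])
        assert weighted_alt_fraction(col2, "C", "+") >= before

    @given(q_lo=st.integers(2, 30), q_hi=st.integers(2, 30), refs=st.integers(1, 6))
    @settings(deadline=None, max_examples=60)
    def test_raising_alt_quality_never_decreases_fraction(self, q_lo, q_hi, refs):
        lo, hi = sorted((q_lo, q_hi))
        base = [("A", 25)] * refs
        frac_lo = weighted_alt_fraction(
            make_column(ref="A", forward=[("C", lo)] + base), "C", "+"
        )
        frac_hi = weighted_alt_fraction(
            make_column(ref="A", forward=[("C", hi)] + base), "C", "+"
        )
        assert frac_hi >= frac_lo


class TestKsDistance:
    @pytest.mark.parametrize(
        "frac,genotype,expected",
        [(0.5, "het", 0.0), (1.0, "hom_ref", 1.0), (0.4739, "het", 0.0261)],
    )
    def test_examples(self, frac, genotype, expected):
        assert ks_distance(frac, genotype) == pytest.approx(expected, abs=1e-6)

    def test_distance_bounded_in_unit_interval(self):
        for frac in np.linspace(0, 1, 21):
            for g in GENOTYPES:
                assert 0.0 <= ks_distance(float(frac), g) <= 1.0


class TestCallGenotype:
    def test_clean_hom_alt_high_quality(self):
        col = make_column(ref="A", forward=[("C", 30)] * 20, reverse=[("C", 30)] * 20)
        call = call_genotype(col)
        assert call.genotype == "hom_alt"
        assert call.tier == "high_quality"

    def test_single_strand_evidence_not_variant(self):
        # forward het-like, reverse all reference: the strand rule vetoes
        col = make_column(
            ref="A",
            forward=[("C", 30)] * 10 + [("A", 30)] * 10,
            reverse=[("A", 30)] * 20,
        )
        call = call_genotype(col, mode="standard")
        assert not call.is_variant

    def test_variant_consensus_lenient_tier(self):
        # pooled fraction ~0.35 with 2 alt observations per strand
        forward = [("C", 30)] * 2 + [("A", 30)] * 4
        reverse = [("C", 30)] * 5 + [("A", 30)] * 9
        col = make_column(ref="A", forward=forward, reverse=reverse)
        thresholds = CallerThresholds(lenient_max_distance=0.2)
        call = call_genotype(col, thresholds, mode="variant_consensus")
        assert call.genotype == "het"
        assert call.tier == "lenient"

    def test_variant_consensus_requires_alt_on_both_strands(self):
        forward = [("C", 30)] * 1 + [("A", 30)] * 5
        reverse = [("C", 30)] * 8 + [("A", 30)] * 6
        col = make_column(ref="A", forward=forward, reverse=reverse)
        call = call_genotype(col, mode="variant_consensus")
        assert call.tier != "lenient"

    def test_empty_column_is_no_call(self):
        call = call_genotype(make_column(ref="A"))
        assert call.tier == "no_call"

    def test_oracle_equivalence_small_enumeration(self):
        """Standard-mode calls match the exhaustive brute-force minimizer on
        a compact enumeration (the full sweep lives in the acceptance suite)."""
        thresholds = CallerThresholds(strict_max_distance=0.25, lenient_max_distance=0.25)
        for n_f, n_r in itertools.product(range(0, 7), range(0, 7)):
            for a_f, a_r in itertools.product(range(n_f + 1), range(n_r + 1)):
                fwd = [("C", 30)] * a_f + [("A", 30)] * (n_f - a_f)
                rev = [("C", 20)] * a_r + [("A", 35)] * (n_r - a_r)
                col = make_column(ref="A", forward=fwd, reverse=rev)
                call = call_genotype(col, thresholds, mode="standard", alt="C")
                if n_f == 0 or n_r == 0:
                    assert call.tier == "no_call"
                    continue
                g_f, d_f = oracle_genotype_per_strand(fwd, "C")
                g_r, d_r = oracle_genotype_per_strand(rev, "C")
                hq = (
                    g_f == g_r
                    and d_f <= thresholds.strict_max_distance
                    and d_r <= thresholds.strict_max_distance
                    and n_f >= thresholds.min_depth_per_strand
                    and n_r >= thresholds.min_depth_per_strand
                )
                if hq:
                    assert call.tier == "high_quality"
                    assert call.genotype == g_f
                else:
                    assert call.tier == "no_call"


class TestCallSomatic:
    def _tumor_het(self, tier="lenient"):
        col = make_column(
            ref="A", forward=[("C", 30)] * 10 + [("A", 30)] * 10,
            reverse=[("C", 30)] * 10 + [("A", 30)] * 10,
        )
        mode = "variant_consensus" if tier == "lenient" else "standard"
        return call_genotype(col, mode=mode)

    def _normal(self, kind):
        if kind == "hom_ref":
            col = make_column(ref="A", forward=[("A", 30)] * 15, reverse=[("A", 30)] * 15)
            return call_genotype(col)
        if kind == "het":
            col = make_column(
                ref="A", forward=[("C", 30)] * 7 + [("A", 30)] * 8,
                reverse=[("C", 30)] * 8 + [("A", 30)] * 7,
            )
            return call_genotype(col)
        col = make_column(ref="A", forward=[("A", 30)] * 2, reverse=[("A", 30)] * 1)
        return call_genotype(col)  # low depth: no_call tier

    def test_tumor_variant_over_clean_normal_is_somatic(self):
        result = call_somatic(self._tumor_het(), self._normal("hom_ref"))
        assert result.somatic

    def test_germline_het_not_somatic(self):
        result = call_somatic(self._tumor_het(), self._normal("het"))
        assert not result.somatic
        assert "germline" in result.filter_notes

    def test_low_depth_normal_is_ambiguous(self):
        result = call_somatic(self._tumor_het(), self._normal("lowdepth"))
        assert not result.somatic
        assert "ambiguous_normal" in result.filter_notes

    def test_locus_mismatch_raises(self):
        tumor = self._tumor_het()
        normal = self._normal("hom_ref")
        normal.pos += 1
        with pytest.raises(PairingError):
            call_somatic(tumor, normal)


class TestDualCallerIntersection:
    def _call(self, pos, alt="C"):
        col = make_column(ref="A", pos=pos, forward=[(alt, 30)] * 10, reverse=[(alt, 30)] * 10)
        return call_genotype(col)

    def test_identical_sets(self):
        calls = [self._call(p) for p in (10, 20, 30)]
        inter, union = dual_caller_intersection(calls, calls)
        assert [c.pos for c in inter] == [10, 20, 30]
        assert [c.pos for c in union] == [10, 20, 30]

    def test_disjoint_sets_empty_intersection(self):
        a = [self._call(10)]
        b = [self._call(20)]
        inter, union = dual_caller_intersection(a, b)
        assert inter == []
        assert [c.pos for c in union] == [10, 20]

    def test_partial_overlap(self):
        a = [self._call(p) for p in (1, 2, 3)]
        b = [self._call(p) for p in (2, 3, 4)]
        inter, union = dual_caller_intersection(a, b)
        assert [c.pos for c in inter] == [2, 3]
        assert [c.pos for c in union] == [1, 2, 3, 4]
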