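import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coreppi.evaluation import (
    GS_NEGATIVE_SIZE,
    GS_POSITIVE_SIZE,
    LikelihoodInputs,
    annotation_hit_ratio,
    count_gs_hits,
    likelihood_ratio,
    overlap_stats,
    reference_hit_ratio,
)
from coreppi.graph_io import ReferenceSets
from coreppi.prediction import PredictionEntry, PredictionSet


def pred_of(pairs) -> PredictionSet:
    return PredictionSet(entries={
        tuple(sorted(p)): PredictionEntry(h=1, sources=[("C", 0)]) for p in pairs
    })


class TestLikelihoodRatio:
    def test_proportional_inputs_give_exactly_one(self):
        inputs = LikelihoodInputs(p_plus=GS_POSITIVE_SIZE, p_minus=GS_NEGATIVE_SIZE)
        assert likelihood_ratio(inputs) == 1.0

    def test_against_exact_fraction_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            p_plus = int(rng.integers(0, 500))
            p_minus = int(rng.integers(1, 5000))
            expected = Fraction(p_plus, GS_POSITIVE_SIZE) / Fraction(
                p_minus, GS_NEGATIVE_SIZE
            )
            got = likelihood_ratio(LikelihoodInputs(p_plus, p_minus))
            assert got == pytest.approx(float(expected), rel=1e-12)

    def test_zero_positive_hits_give_zero(self):
        assert likelihood_ratio(LikelihoodInputs(0, 17)) == 0.0

    def test_no_negative_hits_is_flagged_infinite(self):
        assert math.isinf(likelihood_ratio(LikelihoodInputs(3, 0)))

    def test_no_hits_at_all_is_undefined(self):
        assert math.isnan(likelihood_ratio(LikelihoodInputs(0, 0)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            LikelihoodInputs(-1, 5)

    @given(st.integers(1, 200), st.integers(1, 2000), st.integers(1, 50))
    def test_homogeneous_in_hit_counts(self, p_plus, p_minus, scale):
        base = likelihood_ratio(LikelihoodInputs(p_plus, p_minus))
        scaled = likelihood_ratio(LikelihoodInputs(p_plus * scale, p_minus * scale))
        assert scaled == pytest.approx(base, rel=1e-12)


class TestCountGsHits:
    def test_disjoint_prediction_has_no_hits(self):
        refs = ReferenceSets(gs_positive={("X", "Y")}, gs_negative={("U", "V")})
        inputs = count_gs_hits(pred_of([("A", "B")]), refs)
        assert (inputs.p_plus, inputs.p_minus) == (0, 0)

    def test_prediction_inside_positive_set(self):
        refs = ReferenceSets(
            gs_positive={("A", "B"), ("C", "D"), ("E", "F")}, gs_negative={("U", "V")}
        )
        inputs = count_gs_hits(pred_of([("A", "B"), ("C", "D")]), refs)
        assert (inputs.p_plus, inputs.p_minus) == (2, 0)
        assert (inputs.g_plus, inputs.g_minus) == (3, 1)

    def test_standard_sizes_flag_uses_published_constants(self):
        refs = ReferenceSets(gs_positive={("A", "B")}, gs_negative={("U", "V")})
        inputs = count_gs_hits(pred_of([("A", "B")]), refs, use_standard_sizes=True)
        assert (inputs.g_plus, inputs.g_minus) == (GS_POSITIVE_SIZE, GS_NEGATIVE_SIZE)

    def test_random_sets_match_membership_scan(self):
        rng = np.random.default_rng(29)
        names = [f"P{i}" for i in range(30)]

        def random_pairs(n):
            out = set()
            while len(out) < n:
                a, b = rng.choice(names, size=2, replace=False)
                out.add(tuple(sorted((a, b))))
            return out

        pos = random_pairs(40)
        neg = random_pairs(60) - pos
        pred = pred_of(random_pairs(50))
        inputs = count_gs_hits(pred, ReferenceSets(gs_positive=pos, gs_negative=neg))
        assert inputs.p_plus == sum(1 for p in pred.pairs() if p in pos)
        assert inputs.p_minus == sum(1 for p in pred.pairs() if p in neg)


class TestReferenceHitRatio:
    def test_subset_hits_100_percent(self):
        pred = pred_of([("A", "B"), ("C", "D")])
        assert reference_hit_ratio(pred, {("A", "B"), ("C", "D"), ("E", "F")}) == 100.0

    def test_disjoint_hits_0_percent(self):
        assert reference_hit_ratio(pred_of([("A", "B")]), {("X", "Y")}) == 0.0

    def test_empty_prediction_set_is_an_error(self):
        with pytest.raises(ValueError):
            reference_hit_ratio(PredictionSet(), {("A", "B")})

    def test_random_instances_match_brute_count(self):
        rng = np.random.default_rng(31)
        names = [f"P{i}" for i in range(20)]
        pairs = [tuple(sorted(rng.choice(names, size=2, replace=False)))
                 for _ in range(60)]
        pred = pred_of(pairs[:30])
        ref = set(pairs[15:])
        expected = 100.0 * sum(1 for p in pred.pairs() if p in ref) / len(pred)
        assert reference_hit_ratio(pred, ref) == pytest.approx(expected)


class TestOverlapStats:
    def test_published_sizes_give_33_percent(self):
        # two pair sets of sizes 928 and 465 sharing 344 elements
        shared = {(f"s{i}", f"t{i}") for i in range(344)}
        a = shared | {(f"a{i}", f"b{i}") for i in range(928 - 344)}
        b = shared | {(f"x{i}", f"y{i}") for i in range(465 - 344)}
        stats = overlap_stats(a, b)
        assert (stats.size_a, stats.size_b) == (928, 465)
        assert stats.intersection == 344
        assert stats.union == 1049
        assert stats.ratio_percent_rounded == 33

    def test_identical_sets_overlap_fully(self):
        a = {("A", "B"), ("C", "D")}
        assert overlap_stats(a, set(a)).ratio_percent == 100.0

    def test_disjoint_sets_overlap_zero(self):
        assert overlap_stats({("A", "B")}, {("C", "D")}).ratio_percent == 0.0

    def test_both_empty_is_zero(self):
        assert overlap_stats(set(), set()).ratio_percent == 0.0

    def test_symmetry_and_inclusion_exclusion(self):
        rng = np.random.default_rng(37)
        names = [f"P{i}" for i in range(25)]
        for _ in range(20):
            mk = lambda n: {
                tuple(sorted(rng.choice(names, size=2, replace=False)))
                for _ in range(n)
            }
            a, b = mk(30), mk(30)
            s1, s2 = overlap_stats(a, b), overlap_stats(b, a)
            assert s1.ratio_percent == s2.ratio_percent
            assert s1.union == len(a) + len(b) - s1.intersection == len(a | b)


class TestAnnotationHitRatio:
    ANN = {
        "A": {("GO:1", "proteasome complex"), ("GO:9", "cytoplasm")},
        "B": {("GO:1", "proteasome complex")},
        "C": {("GO:9", "cytoplasm")},
        "D": {("GO:9", "cytoplasm")},
    }

    def test_shared_complex_term_hits(self):
        hits, ratio = annotation_hit_ratio(pred_of([("A", "B")]), self.ANN)
        assert (hits, ratio) == (1, 100.0)

    def test_shared_non_complex_term_misses(self):
        hits, ratio = annotation_hit_ratio(pred_of([("C", "D")]), self.ANN)
        assert (hits, ratio) == (0, 0.0)

    def test_keyword_match_is_case_insensitive_substring(self):
        ann = {"A": {("GO:2", "Proteasome Core COMPLEX part")},
               "B": {("GO:2", "Proteasome Core COMPLEX part")}}
        hits, _ = annotation_hit_ratio(pred_of([("A", "B")]), ann)
        assert hits == 1

    def test_empty_prediction_set_is_an_error(self):
        with pytest.raises(ValueError):
            annotation_hit_ratio(PredictionSet(), self.ANN)

    def test_matches_exhaustive_term_intersection_oracle(self):
        rng = np.random.default_rng(41)
        names = [f"P{i}" for i in range(15)]
        terms = [("GO:1", "spliceosomal complex"), ("GO:2", "nucleus"),
                 ("GO:3", "ribosome complex assembly"), ("GO:4", "membrane")]
        ann = {
            n: {terms[i] for i in rng.choice(4, size=int(rng.integers(1, 4)),
                                             replace=False)}
            for n in names
        }
        pairs = {tuple(sorted(rng.choice(names, size=2, replace=False)))
                 for _ in range(40)}
        hits, ratio = annotation_hit_ratio(pred_of(pairs), ann)
        expected = 0
        for a, b in pairs:
            for term in ann[a]:
                if term in ann[b] and "complex" in term[1].lower():
                    expected += 1
                    break
        assert hits == expected
        assert ratio == pytest.approx(100.0 * expected / len(pairs))
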