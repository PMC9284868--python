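"""Reference construction, TP/FP/FN classification, scoring, overlap
statistics and mean aggregation."""

import numpy as np
import pytest

from ontomatch_eval import (
    Alignment,
    CuiAnnotationTable,
    Mapping,
    UsageError,
    ValidationError,
    aggregate_means,
    build_cui_reference,
    classify,
    overlap_stats,
    restrict_reference_to_module,
    score,
)
from ontomatch_eval.reporting import round_half_away

from conftest import make_ontology, random_alignment


def table(oid, mapping):
    return CuiAnnotationTable(oid, {k: frozenset(v) for k, v in mapping.items()})


class TestCuiReference:
    def test_single_shared_cui(self):
        ref = build_cui_reference(
            table("A", {"a": {"C1"}}), table("B", {"b": {"C1", "C2"}})
        )
        assert ref.pairs() == {("a", "b")}

    def test_disjoint_cuis_give_empty_reference(self):
        ref = build_cui_reference(
            table("A", {"a": {"C1"}}), table("B", {"b": {"C2"}})
        )
        assert len(ref) == 0

    def test_shared_cui_yields_cross_product(self):
        ref = build_cui_reference(
            table("A", {"a1": {"C1"}, "a2": {"C1"}}), table("B", {"b1": {"C1"}})
        )
        assert ref.pairs() == {("a1", "b1"), ("a2", "b1")}

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            map_a = {
                f"a{i}": {f"C{int(c)}" for c in rng.integers(0, 15, rng.integers(1, 4))}
                for i in range(20)
            }
            map_b = {
                f"b{i}": {f"C{int(c)}" for c in rng.integers(0, 15, rng.integers(1, 4))}
                for i in range(20)
            }
            expected = {
                (a, b)
                for a, ca in map_a.items()
                for b, cb in map_b.items()
                if ca & cb
            }
            ref = build_cui_reference(table("A", map_a), table("B", map_b))
            assert ref.pairs() == expected

    def test_identical_ontology_ids_rejected(self):
        with pytest.raises(UsageError):
            build_cui_reference(table("A", {}), table("A", {}))

    def test_malformed_cui_rejected(self):
        with pytest.raises(ValidationError):
            table("A", {"a": {"X123"}})


class TestRestrictToModule:
    def test_whole_ontologies_leave_reference_unchanged(self):
        mod_a = make_ontology({"r": set(), "a1": {"r"}}, "A")
        mod_b = make_ontology({"r": set(), "b1": {"r"}}, "B")
        ref = Alignment("A", "B", [Mapping("a1", "b1")])
        assert restrict_reference_to_module(ref, mod_a, mod_b) == ref

    def test_filter_by_membership(self):
        mod_a = make_ontology({"r": set(), "a1": {"r"}, "a2": {"r"}, "a3": {"r"}}, "A")
        mod_b = make_ontology(
            {"r": set(), "b1": {"r"}, "b2": {"r"}, "b3": {"r"}, "b4": {"r"}, "b5": {"r"}},
            "B",
        )
        ref = Alignment(
            "A",
            "B",
            [
                Mapping("a1", "b1"),
                Mapping("a2", "b2"),
                Mapping("a3", "b3"),
                Mapping("aX", "b4"),  # source outside the module
                Mapping("aY", "b5"),
            ],
        )
        kept = restrict_reference_to_module(ref, mod_a, mod_b)
        assert kept.pairs() == {("a1", "b1"), ("a2", "b2"), ("a3", "b3")}

    def test_empty_module_empties_reference(self):
        mod_a = make_ontology({"r": set()}, "A")
        mod_b = make_ontology({"r": set(), "b1": {"r"}}, "B")
        ref = Alignment("A", "B", [Mapping("a1", "b1")])
        assert len(restrict_reference_to_module(ref, mod_a, mod_b)) == 0

    def test_pair_mismatch_rejected(self):
        mod_a = make_ontology({"r": set()}, "A")
        mod_b = make_ontology({"r": set()}, "B")
        with pytest.raises(ValidationError):
            restrict_reference_to_module(Alignment("A", "C"), mod_a, mod_b)


class TestClassify:
    def test_equal_alignments_have_no_errors(self):
        alignment = Alignment("A", "B", [Mapping("a1", "b1")])
        tp, fp, fn = classify(alignment, alignment)
        assert tp == {("a1", "b1")} and not fp and not fn

    def test_empty_alignment_yields_only_false_negatives(self):
        reference = Alignment("A", "B", [Mapping("a1", "b1")])
        tp, fp, fn = classify(Alignment("A", "B"), reference)
        assert not tp and not fp and fn == reference.pairs()

    def test_three_way_partition_example(self):
        m1, m2, m3, m4 = (Mapping(f"a{i}", f"b{i}") for i in range(1, 5))
        alignment = Alignment("A", "B", [m1, m2, m3])
        reference = Alignment("A", "B", [m2, m4])
        tp, fp, fn = classify(alignment, reference)
        assert tp == {m2.pair} and fp == {m1.pair, m3.pair} and fn == {m4.pair}

    def test_partition_property_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            alignment = random_alignment(rng, int(rng.integers(0, 50)))
            reference = random_alignment(rng, int(rng.integers(0, 50)))
            tp, fp, fn = classify(alignment, reference)
            assert tp | fp == alignment.pairs()
            assert tp | fn == reference.pairs()
            assert len(tp) + len(fp) == len(alignment.pairs())
            assert len(tp) + len(fn) == len(reference.pairs())
            assert not (tp & fp) and not (tp & fn) and not (fp & fn)

    def test_pair_order_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            classify(Alignment("A", "B"), Alignment("B", "A"))


class TestScore:
    def test_perfect(self):
        result = score(1, 0, 0)
        assert result.precision == result.recall == result.f_measure == 1.0

    def test_hand_arithmetic(self):
        result = score(2, 2, 6)
        assert result.precision == 0.5
        assert result.recall == 0.25
        assert result.f_measure == pytest.approx(1 / 3)

    def test_all_wrong_is_zero_not_undefined(self):
        result = score(0, 5, 5)
        assert result.precision == 0.0
        assert result.recall == 0.0
        assert result.f_measure == 0.0

    def test_undefined_markers_distinct_from_zero(self):
        empty_alignment = score(0, 0, 3)
        assert empty_alignment.precision is None
        assert empty_alignment.recall == 0.0
        empty_reference = score(0, 3, 0)
        assert empty_reference.recall is None
        assert empty_reference.f_measure is None

    def test_f_equals_p_when_p_equals_r(self):
        result = score(3, 2, 2)
        assert result.f_measure == pytest.approx(result.precision)

    def test_f_bounded_by_sum(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            tp, fp, fn = (int(x) for x in rng.integers(0, 20, 3))
            result = score(tp, fp, fn)
            if result.f_measure is not None:
                assert result.f_measure <= min(
                    1.0, result.precision + result.recall
                ) + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(UsageError):
            score(-1, 0, 0)


def synthetic_overlap(size_a: int, size_b: int, intersection: int):
    """Two reference alignments with prescribed sizes and intersection."""
    shared = [Mapping(f"s{i}", f"t{i}") for i in range(intersection)]
    only_a = [Mapping(f"xa{i}", f"ya{i}") for i in range(size_a - intersection)]
    only_b = [Mapping(f"xb{i}", f"yb{i}") for i in range(size_b - intersection)]
    return (
        Alignment("A", "B", shared + only_a),
        Alignment("A", "B", shared + only_b),
    )


class TestOverlapStats:
    @pytest.mark.parametrize(
        "size_a,size_b,intersection,expected_pct",
        [
            (3_861, 1_750, 776, 28),  # ORDO-SNOMED CT, whole ontologies
            (19_309, 16_290, 10_195, 57),  # NCIt-SNOMED CT, whole ontologies
            (35, 7, 3, 14),  # ORDO-SNOMED CT, modules
        ],
    )
    def test_weighted_harmonic_mean_reproduces_published_values(
        self, size_a, size_b, intersection, expected_pct
    ):
        ref_a, ref_b = synthetic_overlap(size_a, size_b, intersection)
        stats = overlap_stats(ref_a, ref_b)
        assert stats.intersection == intersection
        assert (
            round_half_away(100 * stats.weighted_harmonic_mean) == expected_pct
        )

    def test_identical_references_give_100_percent(self):
        ref = Alignment("A", "B", [Mapping("a", "b")])
        assert overlap_stats(ref, ref).weighted_harmonic_mean == 1.0

    def test_symmetric_harmonic_mean(self):
        ref_a, ref_b = synthetic_overlap(40, 10, 5)
        assert (
            overlap_stats(ref_a, ref_b).weighted_harmonic_mean
            == overlap_stats(ref_b, ref_a).weighted_harmonic_mean
        )

    def test_harmonic_mean_equals_harmonic_mean_of_proportions(self):
        ref_a, ref_b = synthetic_overlap(30, 20, 6)
        stats = overlap_stats(ref_a, ref_b)
        pa, pb = stats.proportion_a, stats.proportion_b
        assert stats.weighted_harmonic_mean == pytest.approx(
            2 * pa * pb / (pa + pb)
        )

    def test_both_empty_is_undefined(self):
        stats = overlap_stats(Alignment("A", "B"), Alignment("A", "B"))
        assert stats.weighted_harmonic_mean is None


class TestAggregateMeans:
    def test_single_result_is_itself(self):
        result = score(2, 2, 6)
        means = aggregate_means([result])
        assert means.loc["all", "precision"] == result.precision
        assert means.loc["all", "f_measure"] == pytest.approx(result.f_measure)

    def test_mean_of_three_f_measures(self):
        # craft results with known f-measures 0.53, 0.43, 0.60 via P=R=F
        def with_f(f):
            # P = R = f gives F = f
            tp = int(round(f * 100))
            return score(tp, 100 - tp, 100 - tp)

        results = [with_f(0.53), with_f(0.43), with_f(0.60)]
        means = aggregate_means(results)
        assert round_half_away(means.loc["all", "f_measure"], 2) == 0.52

    def test_undefined_scores_excluded_not_zeroed(self):
        defined = score(1, 1, 0)
        undefined = score(0, 0, 5)  # precision undefined
        means = aggregate_means([defined, undefined])
        assert means.loc["all", "precision"] == 0.5

    def test_grouping(self):
        means = aggregate_means(
            [score(1, 0, 0), score(1, 1, 0), score(0, 1, 1)],
            groups=["g1", "g1", "g2"],
        )
        assert means.loc["g1", "precision"] == 0.75
        assert means.loc["g2", "precision"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(UsageError):
            aggregate_means([])
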