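"""Top-level-hierarchy consistency analysis and the FP-discarding
filter."""

import numpy as np
import pytest

from ontomatch_eval import (
    Alignment,
    Mapping,
    TopLevelMappingSet,
    ValidationError,
    analyze_alignment,
    build_cui_reference,
    evaluate,
    filter_and_reevaluate,
    load_top_level_mappings,
    mapping_hierarchy_consistent,
    normalize,
    simulate_matcher,
)
from ontomatch_eval.hierarchy import filter_alignment, tp_union_of
from ontomatch_eval.published import curated_top_level_table

from conftest import make_ontology


def stand_in(oid: str, tops: list[str], leaves: dict[str, str] | None = None):
    """Synthetic stand-in ontology with the given top-level classes
    (real terminologies are license-restricted)."""
    edges: dict[str, set[str]] = {"root": set()}
    for top in tops:
        edges[top] = {"root"}
    for leaf, parent in (leaves or {}).items():
        edges[leaf] = {parent}
    return make_ontology(edges, oid)


ORDO_TOPS = [
    f"http://www.orpha.net/ORDO/Orphanet_{c}"
    for c in ("C001", "C010", "C009", "C005", "C023")
]
SNOMED_TOPS = [
    f"http://snomed.info/id/{c}"
    for c in (
        "404684003", "105590001", "308916002", "123037004", "362981000",
        "71388002", "410607006", "373873005", "260787004", "363787002",
        "48176007",
    )
]
NCIT_TOPS = [
    f"http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#{c}"
    for c in (
        "C7057", "C26548", "C20181", "C20189", "C12219",
        "C43431", "C14250", "C1908", "C97325",
    )
]


class TestLoadCuratedTables:
    def test_ordo_snomedct_has_three_pairs(self):
        tlms = load_top_level_mappings(
            curated_top_level_table("ORDO-SNOMEDCT"),
            stand_in("ORDO", ORDO_TOPS),
            stand_in("SNOMEDCT", SNOMED_TOPS),
        )
        assert len(tlms.pairs) == 3

    def test_ncit_snomedct_has_thirteen_pairs(self):
        tlms = load_top_level_mappings(
            curated_top_level_table("NCIt-SNOMEDCT"),
            stand_in("NCIt", NCIT_TOPS),
            stand_in("SNOMEDCT", SNOMED_TOPS),
        )
        assert len(tlms.pairs) == 13

    def test_many_to_many_pairs_allowed(self):
        tlms = load_top_level_mappings(
            curated_top_level_table("NCIt-SNOMEDCT"),
            stand_in("NCIt", NCIT_TOPS),
            stand_in("SNOMEDCT", SNOMED_TOPS),
        )
        sources = [a for a, _ in tlms.pairs]
        assert any(sources.count(a) > 1 for a in sources)

    def test_non_top_level_row_rejected(self, tmp_path):
        onto_a = stand_in("A", ["tA"], {"leaf": "tA"})
        onto_b = stand_in("B", ["tB"])
        path = tmp_path / "tl.tsv"
        path.write_text("iri_a\tiri_b\nleaf\ttB\n")
        with pytest.raises(ValidationError, match="leaf"):
            load_top_level_mappings(path, onto_a, onto_b)


@pytest.fixture
def two_category_setup():
    """Two ontologies with two categories each; only (tA1, tB1) matched."""
    onto_a = stand_in(
        "A", ["tA1", "tA2"], {"a1": "tA1", "a2": "tA2", "a1x": "a1"}
    )
    onto_b = stand_in(
        "B", ["tB1", "tB2"], {"b1": "tB1", "b2": "tB2", "b1x": "b1"}
    )
    tlms = TopLevelMappingSet(pair=("A", "B"), pairs=frozenset({("tA1", "tB1")}))
    return onto_a, onto_b, tlms


class TestConsistency:
    def test_cross_category_mapping_is_inconsistent(self, two_category_setup):
        onto_a, onto_b, tlms = two_category_setup
        assert not mapping_hierarchy_consistent(
            Mapping("a1", "b2"), onto_a, onto_b, tlms
        )

    def test_same_matched_category_is_consistent(self, two_category_setup):
        onto_a, onto_b, tlms = two_category_setup
        assert mapping_hierarchy_consistent(
            Mapping("a1x", "b1x"), onto_a, onto_b, tlms
        )

    def test_mapping_between_matched_top_levels_is_consistent(
        self, two_category_setup
    ):
        onto_a, onto_b, tlms = two_category_setup
        assert mapping_hierarchy_consistent(
            Mapping("tA1", "tB1"), onto_a, onto_b, tlms
        )

    def test_any_matching_ancestor_pair_suffices(self):
        # multi-inheritance: one plausible category match keeps the mapping
        onto_a = stand_in("A", ["tA1", "tA2"])
        onto_a = make_ontology(
            {
                "root": set(),
                "tA1": {"root"},
                "tA2": {"root"},
                "a": {"tA1", "tA2"},
            },
            "A",
        )
        onto_b = stand_in("B", ["tB1"], {"b": "tB1"})
        tlms = TopLevelMappingSet(("A", "B"), frozenset({("tA1", "tB1")}))
        assert mapping_hierarchy_consistent(Mapping("a", "b"), onto_a, onto_b, tlms)


class TestAnalyzeAlignment:
    def test_all_consistent(self, two_category_setup):
        onto_a, onto_b, tlms = two_category_setup
        alignment = Alignment("A", "B", [Mapping("a1", "b1")])
        result = analyze_alignment(alignment, onto_a, onto_b, tlms)
        assert result.inconsistent_count == 0
        assert result.proportion_inconsistent == 0.0

    def test_counts_with_tp_union(self, two_category_setup):
        onto_a, onto_b, tlms = two_category_setup
        # 10 mappings: 4 inconsistent (cross-category), 3 of those not TP
        consistent = [Mapping(f"a1", f"b1")] + [
            Mapping("a1x", "b1x"), Mapping("tA1", "tB1"),
            Mapping("a1", "b1x"), Mapping("a1x", "b1"), Mapping("tA1", "b1"),
        ]
        inconsistent = [
            Mapping("a1", "b2"), Mapping("a2", "b1"),
            Mapping("a2", "b2"), Mapping("a1x", "b2"),
        ]
        alignment = Alignment("A", "B", consistent + inconsistent)
        assert len(alignment) == 10
        tp_union = {("a1", "b2")}  # one inconsistent mapping is a TP somewhere
        result = analyze_alignment(alignment, onto_a, onto_b, tlms, tp_union)
        assert result.inconsistent_count == 4
        assert result.inconsistent_fp_count == 3
        assert result.proportion_inconsistent == pytest.approx(0.4)

    def test_unresolvable_bucket(self, two_category_setup):
        onto_a, onto_b, tlms = two_category_setup
        alignment = Alignment("A", "B", [Mapping("a1", "b1"), Mapping("ghost", "b1")])
        result = analyze_alignment(alignment, onto_a, onto_b, tlms)
        assert len(result.unresolvable_mappings) == 1
        assert result.inconsistent_count == 0

    def test_empty_alignment_has_undefined_proportions(self, two_category_setup):
        onto_a, onto_b, tlms = two_category_setup
        result = analyze_alignment(Alignment("A", "B"), onto_a, onto_b, tlms)
        assert result.proportion_inconsistent is None

    def test_partition_covers_alignment(self, two_category_setup):
        onto_a, onto_b, tlms = two_category_setup
        alignment = Alignment(
            "A", "B", [Mapping("a1", "b1"), Mapping("a1", "b2"), Mapping("zz", "b1")]
        )
        result = analyze_alignment(alignment, onto_a, onto_b, tlms)
        union = (
            result.consistent_mappings
            | result.inconsistent_mappings
            | result.unresolvable_mappings
        )
        assert union == alignment.mappings


class TestFilterAndReevaluate:
    def test_no_inconsistent_mappings_changes_nothing(self, two_category_setup):
        onto_a, onto_b, tlms = two_category_setup
        alignment = Alignment("A", "B", [Mapping("a1", "b1"), Mapping("a1x", "b1x")])
        reference = Alignment("A", "B", [Mapping("a1", "b1")], provenance="ref")
        result = analyze_alignment(alignment, onto_a, onto_b, tlms)
        (before, after) = filter_and_reevaluate(alignment, result, [reference])["ref"]
        assert before == after

    def test_discarding_fp_raises_precision_keeps_recall(self, two_category_setup):
        onto_a, onto_b, tlms = two_category_setup
        # tp=2, fp=3 of which 2 inconsistent and not TP -> precision
        # rises from 2/5 to 2/3; recall untouched
        tps = [Mapping("a1", "b1"), Mapping("a1x", "b1x")]
        fps_consistent = [Mapping("a1", "b1x")]
        fps_inconsistent = [Mapping("a1", "b2"), Mapping("a2", "b1")]
        alignment = Alignment("A", "B", tps + fps_consistent + fps_inconsistent)
        reference = Alignment("A", "B", tps, provenance="ref")
        tp_union = tp_union_of(alignment, [reference])
        result = analyze_alignment(alignment, onto_a, onto_b, tlms, tp_union)
        (before, after) = filter_and_reevaluate(alignment, result, [reference])["ref"]
        assert before.precision == pytest.approx(0.4)
        assert after.precision == pytest.approx(2 / 3)
        assert before.recall == after.recall == 1.0

    def test_inconsistent_tp_in_any_reference_is_kept(self, two_category_setup):
        onto_a, onto_b, tlms = two_category_setup
        odd_tp = Mapping("a1", "b2")  # inconsistent yet present in one reference
        alignment = Alignment("A", "B", [odd_tp, Mapping("a2", "b2")])
        ref1 = Alignment("A", "B", [odd_tp], provenance="ref1")
        ref2 = Alignment("A", "B", [Mapping("a1", "b1")], provenance="ref2")
        tp_union = tp_union_of(alignment, [ref1, ref2])
        result = analyze_alignment(alignment, onto_a, onto_b, tlms, tp_union)
        filtered = filter_alignment(alignment, result, tp_union)
        assert odd_tp in filtered
        assert Mapping("a2", "b2") not in filtered

    def test_reference_pair_mismatch_rejected(self, two_category_setup):
        onto_a, onto_b, tlms = two_category_setup
        alignment = Alignment("A", "B", [Mapping("a1", "b1")])
        result = analyze_alignment(alignment, onto_a, onto_b, tlms)
        with pytest.raises(ValidationError):
            filter_and_reevaluate(alignment, result, [Alignment("B", "A")])

    def test_guarantees_on_synthetic_scenarios(self, small_scenario, small_config):
        pair = ("SYNTH-A", "SYNTH-B")
        ground_truth = normalize(small_scenario.ground_truth, pair)
        cui_ref = normalize(
            build_cui_reference(
                small_scenario.cui_table_a, small_scenario.cui_table_b
            ),
            pair,
        )
        for seed in (1, 2, 3):
            sim = simulate_matcher(small_scenario, small_config, seed=seed)
            alignment = normalize(sim.alignment, pair)
            references = [ground_truth, cui_ref]
            tp_union = tp_union_of(alignment, references)
            result = analyze_alignment(
                alignment,
                small_scenario.ontology_a,
                small_scenario.ontology_b,
                small_scenario.top_level_mappings,
                tp_union,
            )
            for before, after in filter_and_reevaluate(
                alignment, result, references
            ).values():
                assert after.recall == before.recall
                assert after.precision >= before.precision
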