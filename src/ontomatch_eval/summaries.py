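"""Recompute the published evaluation's derived summary statistics with
this package's own operations.

The printed primary numbers (alignment sizes, reference sizes and
intersections, inconsistent-mapping counts) are inputs from
:mod:`ontomatch_eval.published`; everything derived — weighted
harmonic-mean overlaps, inconsistency proportions, mean alignment sizes —
is recomputed at run time by constructing equivalent in-memory objects
and running the evaluation operations over them, never by copying the
derived values.
"""

from __future__ import annotations

import numpy as np

from .alignments import Alignment, Mapping
from .evaluation import overlap_stats
from .hierarchy import TopLevelMappingSet, analyze_alignment
from .ontology import Ontology, OntologyClass
from .published import (
    ALIGNMENT_SIZES_WHOLE,
    INCONSISTENT_COUNTS_WHOLE,
    PRINTED_INCONSISTENT_PERCENTAGES_WHOLE,
    REFERENCE_OVERLAPS,
)
from .reporting import round_half_away


def _alignments_with_overlap(
    size_a: int, size_b: int, intersection: int
) -> tuple[Alignment, Alignment]:
    """Two reference alignments realizing the given sizes/intersection."""
    shared = [Mapping(f"urn:s:{i}", f"urn:t:{i}") for i in range(intersection)]
    only_a = [
        Mapping(f"urn:oa:{i}", f"urn:pa:{i}") for i in range(size_a - intersection)
    ]
    only_b = [
        Mapping(f"urn:ob:{i}", f"urn:pb:{i}") for i in range(size_b - intersection)
    ]
    return (
        Alignment("A", "B", shared + only_a),
        Alignment("A", "B", shared + only_b),
    )


def recomputed_overlap_percent(pair: str, scope: str) -> float:
    """Weighted harmonic-mean overlap (percent) between the UMLS-derived
    and BioPortal-derived reference alignments of one pair/scope,
    recomputed by running ``overlap_stats`` on alignments with the
    published sizes and intersection."""
    size_umls, size_bioportal, intersection = REFERENCE_OVERLAPS[(pair, scope)]
    ref_a, ref_b = _alignments_with_overlap(size_umls, size_bioportal, intersection)
    stats = overlap_stats(ref_a, ref_b)
    return round_half_away(100 * stats.weighted_harmonic_mean)


def _two_category_scenario(
    n_consistent: int, n_inconsistent: int
) -> tuple[Ontology, Ontology, TopLevelMappingSet, Alignment]:
    """A minimal pair with one matched and one unmatched category, and an
    alignment with the requested consistent/inconsistent mapping counts."""

    def side(oid: str, n: int) -> Ontology:
        classes = {
            "urn:root": OntologyClass(iri="urn:root"),
            "urn:tm": OntologyClass(iri="urn:tm", parent_iris=frozenset({"urn:root"})),
            "urn:tu": OntologyClass(iri="urn:tu", parent_iris=frozenset({"urn:root"})),
        }
        for i in range(n):
            parent = "urn:tm" if i < n_consistent else "urn:tu"
            iri = f"urn:{oid}:{i}"
            classes[iri] = OntologyClass(iri=iri, parent_iris=frozenset({parent}))
        return Ontology(ontology_id=oid, classes=classes, root_iri="urn:root")

    total = n_consistent + n_inconsistent
    onto_a, onto_b = side("A", total), side("B", total)
    tlms = TopLevelMappingSet(pair=("A", "B"), pairs=frozenset({("urn:tm", "urn:tm")}))
    alignment = Alignment(
        "A", "B", [Mapping(f"urn:A:{i}", f"urn:B:{i}") for i in range(total)]
    )
    return onto_a, onto_b, tlms, alignment


def recomputed_inconsistency_percent(system: str, pair: str) -> float:
    """Proportion (percent) of a matcher's whole-ontology alignment whose
    classes' top-level ancestors were not manually matched, recomputed by
    running the hierarchy analysis over a constructed alignment with the
    published total and inconsistent counts."""
    total = ALIGNMENT_SIZES_WHOLE[(system, pair)]
    inconsistent, _ = INCONSISTENT_COUNTS_WHOLE[(system, pair)]
    onto_a, onto_b, tlms, alignment = _two_category_scenario(
        total - inconsistent, inconsistent
    )
    result = analyze_alignment(alignment, onto_a, onto_b, tlms)
    assert result.inconsistent_count == inconsistent
    return round_half_away(100 * result.proportion_inconsistent)


def mean_alignment_size(pair: str) -> float:
    """Mean number of mappings the three matchers exposed for one pair
    (whole ontologies)."""
    sizes = [
        size for (system, p), size in ALIGNMENT_SIZES_WHOLE.items() if p == pair
    ]
    return float(np.mean(sizes))


def mean_inconsistency_percentages() -> tuple[float, float]:
    """Average whole-ontology inconsistency percentage over all nine
    system/pair combinations, and its complement (the share of mappings
    whose top-level hierarchies matched)."""
    mean_pct = float(np.mean(PRINTED_INCONSISTENT_PERCENTAGES_WHOLE))
    return round_half_away(mean_pct), round_half_away(100 - mean_pct)
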