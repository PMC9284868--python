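"""Top-level-hierarchy consistency analysis of mappings.

Lexical matchers happily map two classes labelled "bone fracture" even
when one is a clinical finding and the other a body structure.  This
module implements a reference-free plausibility check: a mapping is
*hierarchy-consistent* when at least one pair of its classes' top-level
ancestors appears in a manually curated table of matched top-level
classes.  Mappings failing the check are candidate errors; those that are
additionally not a true positive against any available reference
alignment can be discarded, which raises precision and, because only
false positives are removed, never changes recall.

The existential rule (ANY matching top-level ancestor pair suffices) is
the conservative choice under multiple inheritance: a mapping with one
plausible category match is never discarded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .alignments import Alignment, Mapping
from .errors import FormatError, ValidationError
from .evaluation import EvaluationResult, evaluate
from .ontology import Ontology, top_level_ancestors, top_level_classes


@dataclass(frozen=True)
class TopLevelMappingSet:
    """Manually curated pairs of matched top-level classes for one
    ontology pair; many-to-many pairs are allowed."""

    pair: tuple[str, str]
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))


def load_top_level_mappings(
    path, onto_a: Ontology, onto_b: Ontology
) -> TopLevelMappingSet:
    """Read a TSV table (columns ``iri_a``, ``iri_b``) of matched
    top-level classes, validating that every IRI really is a top-level
    class of its ontology."""
    tops_a = top_level_classes(onto_a)
    tops_b = top_level_classes(onto_b)
    pairs = set()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != ("iri_a", "iri_b"):
            raise FormatError(
                f"{path}: expected header ('iri_a', 'iri_b'), got {reader.fieldnames}"
            )
        for line_no, row in enumerate(reader, start=2):
            iri_a, iri_b = row["iri_a"], row["iri_b"]
            if iri_a not in tops_a:
                raise ValidationError(
                    f"{path}:{line_no}: {iri_a!r} is not a top-level class "
                    f"of {onto_a.ontology_id}"
                )
            if iri_b not in tops_b:
                raise ValidationError(
                    f"{path}:{line_no}: {iri_b!r} is not a top-level class "
                    f"of {onto_b.ontology_id}"
                )
            pairs.add((iri_a, iri_b))
    return TopLevelMappingSet(
        pair=(onto_a.ontology_id, onto_b.ontology_id), pairs=frozenset(pairs)
    )


def write_top_level_mappings(tlms: TopLevelMappingSet, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["iri_a", "iri_b"])
        for iri_a, iri_b in sorted(tlms.pairs):
            writer.writerow([iri_a, iri_b])


def mapping_hierarchy_consistent(
    mapping: Mapping,
    onto_a: Ontology,
    onto_b: Ontology,
    tlms: TopLevelMappingSet,
) -> bool:
    """True iff some pair of the classes' top-level ancestors is in the
    curated table.  A top-level class counts as its own top-level
    ancestor, so a mapping between two matched top-level classes is
    consistent."""
    tops_a = top_level_ancestors(onto_a, mapping.source_iri)
    tops_b = top_level_ancestors(onto_b, mapping.target_iri)
    return any(
        (ta, tb) in tlms.pairs for ta in tops_a for tb in tops_b
    )


@dataclass(frozen=True)
class HierarchyAnalysisResult:
    """Partition of an alignment by top-level-hierarchy consistency.

    ``inconsistent_fp_count`` counts the inconsistent mappings that are
    not a TP against any supplied reference — the ones eligible for
    removal.  ``unresolvable_mappings`` hold classes missing from the
    ontologies and belong to neither partition.  Proportions are over the
    analyzed alignment size and are ``None`` for an empty alignment.
    """

    consistent_mappings: frozenset[Mapping]
    inconsistent_mappings: frozenset[Mapping]
    unresolvable_mappings: frozenset[Mapping]
    inconsistent_count: int
    inconsistent_fp_count: int
    proportion_inconsistent: float | None
    proportion_inconsistent_fp: float | None


def analyze_alignment(
    alignment: Alignment,
    onto_a: Ontology,
    onto_b: Ontology,
    tlms: TopLevelMappingSet,
    tp_union: set[tuple[str, str]] | None = None,
) -> HierarchyAnalysisResult:
    """Classify every mapping as hierarchy-consistent or not.

    ``tp_union`` is the set of (source, target) pairs that are TP against
    at least one reference alignment; inconsistent mappings outside it
    are the removable false positives.
    """
    tp_union = tp_union or set()
    consistent, inconsistent, unresolvable = set(), set(), set()
    for mapping in alignment.mappings:
        if mapping.source_iri not in onto_a or mapping.target_iri not in onto_b:
            unresolvable.add(mapping)
        elif mapping_hierarchy_consistent(mapping, onto_a, onto_b, tlms):
            consistent.add(mapping)
        else:
            inconsistent.add(mapping)
    total = len(alignment)
    inconsistent_fp = sum(1 for m in inconsistent if m.pair not in tp_union)
    return HierarchyAnalysisResult(
        consistent_mappings=frozenset(consistent),
        inconsistent_mappings=frozenset(inconsistent),
        unresolvable_mappings=frozenset(unresolvable),
        inconsistent_count=len(inconsistent),
        inconsistent_fp_count=inconsistent_fp,
        proportion_inconsistent=len(inconsistent) / total if total else None,
        proportion_inconsistent_fp=inconsistent_fp / total if total else None,
    )


def tp_union_of(alignment: Alignment, references: list[Alignment]) -> set[tuple[str, str]]:
    """(source, target) pairs of the alignment that are TP against at
    least one of the references."""
    pairs = alignment.pairs()
    union: set[tuple[str, str]] = set()
    for reference in references:
        union |= pairs & reference.pairs()
    return union


def filter_alignment(
    alignment: Alignment,
    result: HierarchyAnalysisResult,
    tp_union: set[tuple[str, str]],
) -> Alignment:
    """Drop the hierarchy-inconsistent mappings that are not TP against
    any reference; mappings that are TP anywhere are kept."""
    removable = {
        m.pair for m in result.inconsistent_mappings if m.pair not in tp_union
    }
    kept = [m for m in alignment.mappings if m.pair not in removable]
    return Alignment(
        alignment.source_ontology_id,
        alignment.target_ontology_id,
        kept,
        provenance=(alignment.provenance + "+hierarchy-filtered").lstrip("+"),
    )


def filter_and_reevaluate(
    alignment: Alignment,
    result: HierarchyAnalysisResult,
    references: list[Alignment],
) -> dict[str, tuple[EvaluationResult, EvaluationResult]]:
    """Re-score after discarding removable inconsistent mappings.

    Returns, per reference label, the (before, after) result pair.
    Because only mappings that are FP against *every* reference are
    removed, recall is identical before and after and precision can only
    go up.
    """
    for reference in references:
        if (reference.source_ontology_id, reference.target_ontology_id) != (
            alignment.source_ontology_id,
            alignment.target_ontology_id,
        ):
            raise ValidationError(
                "references must be normalized to the alignment's pair order"
            )
    tp_union = tp_union_of(alignment, references)
    filtered = filter_alignment(alignment, result, tp_union)
    out: dict[str, tuple[EvaluationResult, EvaluationResult]] = {}
    for index, reference in enumerate(references):
        label = reference.provenance or f"reference-{index}"
        before = evaluate(alignment, reference, label)
        after = evaluate(filtered, reference, label)
        out[label] = (before, after)
    return out
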