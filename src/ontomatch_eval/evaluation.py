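"""Reference-alignment construction and precision/recall/F-measure
evaluation.

A reference alignment is built from UMLS concept unique identifiers
(CUIs): any class pair sharing at least one CUI is a reference mapping.
References are incomplete by nature (a "silver standard"), so true
negatives are never computed — every mapping is classified as TP
(in alignment and reference), FP (alignment only) or FN (reference
only), and

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F-measure = 2 * precision * recall / (precision + recall)

An empty alignment (or reference) makes precision (or recall) undefined;
that is reported as ``None``, a distinct marker, never silently as 0 —
scoring 0 would corrupt means over systems.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from typing import Mapping as TMapping, Sequence

import pandas as pd

from .alignments import Alignment, Mapping
from .errors import FormatError, UsageError, ValidationError
from .ontology import Ontology

logger = logging.getLogger(__name__)

_CUI_PATTERN = re.compile(r"^C\d+$")


@dataclass(frozen=True)
class CuiAnnotationTable:
    """Per-class CUI codes for one ontology; classes without CUIs may be
    absent from the map."""

    ontology_id: str
    cui_map: TMapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for iri, cuis in self.cui_map.items():
            for cui in cuis:
                if not _CUI_PATTERN.match(cui):
                    raise ValidationError(
                        f"{iri}: {cui!r} is not a CUI (expected C + digits)"
                    )


def read_cui_table_tsv(path, ontology_id: str = "") -> CuiAnnotationTable:
    """Read a CUI table: TSV columns ``iri``, ``cuis`` (pipe-separated)."""
    cui_map: dict[str, frozenset[str]] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != ("iri", "cuis"):
            raise FormatError(
                f"{path}: expected header ('iri', 'cuis'), got {reader.fieldnames}"
            )
        for row in reader:
            cuis = frozenset(c for c in row["cuis"].split("|") if c)
            if cuis:
                cui_map[row["iri"]] = cuis
    return CuiAnnotationTable(ontology_id or str(path), cui_map)


def write_cui_table_tsv(table: CuiAnnotationTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["iri", "cuis"])
        for iri in sorted(table.cui_map):
            writer.writerow([iri, "|".join(sorted(table.cui_map[iri]))])


def cui_table_from_ontology(ontology: Ontology) -> CuiAnnotationTable:
    """Collect the CUI annotations carried by an ontology's classes
    (the route used for ontologies that embed their own CUI codes)."""
    cui_map = {
        iri: cls.cuis for iri, cls in ontology.classes.items() if cls.cuis
    }
    return CuiAnnotationTable(ontology.ontology_id, cui_map)


def build_cui_reference(
    table_a: CuiAnnotationTable, table_b: CuiAnnotationTable
) -> Alignment:
    """Reference alignment from shared CUIs: every class pair (a, b) with
    at least one CUI in common becomes an equivalence mapping.  A CUI
    carried by several classes on either side yields all cross pairs."""
    if table_a.ontology_id == table_b.ontology_id:
        raise UsageError("reference requires two distinct ontologies")
    by_cui_b: dict[str, set[str]] = {}
    for iri, cuis in table_b.cui_map.items():
        for cui in cuis:
            by_cui_b.setdefault(cui, set()).add(iri)
    reference = Alignment(
        table_a.ontology_id, table_b.ontology_id, provenance="cui-reference"
    )
    for iri_a, cuis in table_a.cui_map.items():
        targets: set[str] = set()
        for cui in cuis:
            targets |= by_cui_b.get(cui, set())
        for iri_b in targets:
            reference.add(Mapping(source_iri=iri_a, target_iri=iri_b))
    return reference


def restrict_reference_to_module(
    reference: Alignment, module_a: Ontology, module_b: Ontology
) -> Alignment:
    """Module-level reference: drop mappings whose classes fell outside
    the extracted modules."""
    if (
        reference.source_ontology_id != module_a.ontology_id
        or reference.target_ontology_id != module_b.ontology_id
    ):
        raise ValidationError(
            "reference pair order does not match the supplied modules"
        )
    kept = [
        m
        for m in reference.mappings
        if m.source_iri in module_a and m.target_iri in module_b
    ]
    return Alignment(
        reference.source_ontology_id,
        reference.target_ontology_id,
        kept,
        provenance=reference.provenance,
    )


def _check_same_pair(a: Alignment, b: Alignment) -> None:
    if (a.source_ontology_id, a.target_ontology_id) != (
        b.source_ontology_id,
        b.target_ontology_id,
    ):
        raise ValidationError(
            "alignment and reference must be normalized to the same pair order"
        )


def classify(
    alignment: Alignment, reference: Alignment
) -> tuple[set[tuple[str, str]], set[tuple[str, str]], set[tuple[str, str]]]:
    """Partition mappings into TP (in both), FP (alignment only) and FN
    (reference only) on (source, target) identity."""
    _check_same_pair(alignment, reference)
    a, r = alignment.pairs(), reference.pairs()
    return a & r, a - r, r - a


@dataclass(frozen=True)
class EvaluationResult:
    """TP/FP/FN counts with derived scores; ``None`` marks an undefined
    score (empty alignment or empty reference)."""

    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f_measure: float | None
    reference_label: str = ""


def score(tp: int, fp: int, fn: int, reference_label: str = "") -> EvaluationResult:
    """Precision, recall and F-measure from TP/FP/FN counts."""
    if min(tp, fp, fn) < 0:
        raise UsageError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is None or recall is None:
        f_measure = None
    elif precision + recall == 0:
        f_measure = 0.0
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    return EvaluationResult(tp, fp, fn, precision, recall, f_measure, reference_label)


def evaluate(
    alignment: Alignment, reference: Alignment, reference_label: str = ""
) -> EvaluationResult:
    """Classify against a reference and score in one step."""
    tp, fp, fn = classify(alignment, reference)
    return score(len(tp), len(fp), len(fn), reference_label)


@dataclass(frozen=True)
class OverlapStats:
    """Agreement between two reference alignments for the same pair.

    ``weighted_harmonic_mean`` = 2*I / (|A| + |B|) — the harmonic mean of
    the two overlap proportions weighted by reference size; ``None`` when
    both references are empty.
    """

    size_a: int
    size_b: int
    intersection: int
    proportion_a: float | None
    proportion_b: float | None
    weighted_harmonic_mean: float | None


def overlap_stats(ref_a: Alignment, ref_b: Alignment) -> OverlapStats:
    """Overlap between two reference alignments on (source, target)
    identity; symmetric in its arguments."""
    _check_same_pair(ref_a, ref_b)
    pairs_a, pairs_b = ref_a.pairs(), ref_b.pairs()
    inter = len(pairs_a & pairs_b)
    size_a, size_b = len(pairs_a), len(pairs_b)
    return OverlapStats(
        size_a=size_a,
        size_b=size_b,
        intersection=inter,
        proportion_a=inter / size_a if size_a else None,
        proportion_b=inter / size_b if size_b else None,
        weighted_harmonic_mean=(
            2 * inter / (size_a + size_b) if size_a + size_b else None
        ),
    )


def aggregate_means(
    results: Sequence[EvaluationResult],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean precision/recall/F-measure per group (e.g. per ontology pair
    over systems, or per system over pairs).

    Undefined scores are excluded from the means with a logged count,
    never treated as zero.
    """
    if not results:
        raise UsageError("aggregate_means requires at least one result")
    if groups is None:
        groups = ["all"] * len(results)
    if len(groups) != len(results):
        raise UsageError("groups must parallel results")
    undefined = sum(
        1
        for r in results
        if r.precision is None or r.recall is None or r.f_measure is None
    )
    if undefined:
        logger.info(
            "aggregate_means: %d result(s) had undefined scores; excluded",
            undefined,
        )
    frame = pd.DataFrame(
        {
            "group": list(groups),
            "precision": [r.precision for r in results],
            "recall": [r.recall for r in results],
            "f_measure": [r.f_measure for r in results],
        }
    )
    return frame.groupby("group", sort=True).mean(numeric_only=True)
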