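"""Alignment data model, Alignment-format RDF and TSV I/O, normalization
and vote-based consensus.

A mapping is a triple <e, e', r> linking a class of one ontology to a
class of another with a relation (equivalence, in practice) and an
optional confidence in [0, 1].  An alignment is the set of mappings a
matcher (or a reference source) produced for one ontology pair.  Mapping
identity ignores confidence throughout: two matchers that output the same
class pair with different measures agree on the mapping.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence
from xml.sax.saxutils import escape, quoteattr

from rdflib import Graph

from .errors import FormatError, UsageError, ValidationError

logger = logging.getLogger(__name__)

EQUIVALENCE = "equivalence"
SUBSUMES = "subsumes"
SUBSUMED_BY = "subsumed_by"
MORE_GENERIC = "more_generic"
MORE_SPECIFIC = "more_specific"
RELATIONS = (EQUIVALENCE, SUBSUMES, SUBSUMED_BY, MORE_GENERIC, MORE_SPECIFIC)

#: Alignment-format relation symbols <-> model relations.
_SYMBOL_TO_RELATION = {
    "=": EQUIVALENCE,
    ">": SUBSUMES,
    "<": SUBSUMED_BY,
    ">=": MORE_GENERIC,
    "<=": MORE_SPECIFIC,
}
_RELATION_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_RELATION.items()}

_INVERSE = {
    EQUIVALENCE: EQUIVALENCE,
    SUBSUMES: SUBSUMED_BY,
    SUBSUMED_BY: SUBSUMES,
    MORE_GENERIC: MORE_SPECIFIC,
    MORE_SPECIFIC: MORE_GENERIC,
}

ALIGNMENT_NS = "http://knowledgeweb.semanticweb.org/heterogeneity/alignment"


@dataclass(frozen=True)
class Mapping:
    """One correspondence between two classes.

    Equality and hashing ignore ``confidence``: identity is the
    (source, target, relation) triple.
    """

    source_iri: str
    target_iri: str
    relation: str = EQUIVALENCE
    confidence: float = field(default=1.0, compare=False)

    def __post_init__(self) -> None:
        if not self.source_iri or not self.target_iri:
            raise ValidationError("mapping iris must be non-empty")
        if self.relation not in RELATIONS:
            raise ValidationError(f"unknown relation {self.relation!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError("confidence must lie in [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source_iri, self.target_iri)

    def invert(self) -> "Mapping":
        return Mapping(
            source_iri=self.target_iri,
            target_iri=self.source_iri,
            relation=_INVERSE[self.relation],
            confidence=self.confidence,
        )


class Alignment:
    """A set of mappings between two ontologies.

    No two mappings share (source, target, relation); adding a duplicate
    keeps the maximum confidence.
    """

    def __init__(
        self,
        source_ontology_id: str,
        target_ontology_id: str,
        mappings: Iterable[Mapping] = (),
        provenance: str = "",
    ) -> None:
        self.source_ontology_id = source_ontology_id
        self.target_ontology_id = target_ontology_id
        self.provenance = provenance
        self._mappings: dict[tuple[str, str, str], Mapping] = {}
        for mapping in mappings:
            self.add(mapping)

    def add(self, mapping: Mapping) -> None:
        key = (mapping.source_iri, mapping.target_iri, mapping.relation)
        existing = self._mappings.get(key)
        if existing is None or mapping.confidence > existing.confidence:
            self._mappings[key] = mapping

    @property
    def mappings(self) -> set[Mapping]:
        return set(self._mappings.values())

    def pairs(self) -> set[tuple[str, str]]:
        """The (source, target) pairs of the equivalence mappings."""
        return {m.pair for m in self._mappings.values() if m.relation == EQUIVALENCE}

    def sorted_mappings(self) -> list[Mapping]:
        return sorted(
            self._mappings.values(),
            key=lambda m: (m.source_iri, m.target_iri, m.relation),
        )

    def __len__(self) -> int:
        return len(self._mappings)

    def __iter__(self) -> Iterator[Mapping]:
        return iter(self.sorted_mappings())

    def __contains__(self, mapping: Mapping) -> bool:
        key = (mapping.source_iri, mapping.target_iri, mapping.relation)
        return key in self._mappings

    def __eq__(self, other) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.source_ontology_id == other.source_ontology_id
            and self.target_ontology_id == other.target_ontology_id
            and self._mappings.keys() == other._mappings.keys()
        )

    def __repr__(self) -> str:
        return (
            f"Alignment({self.source_ontology_id!r}, "
            f"{self.target_ontology_id!r}, {len(self)} mappings)"
        )


def _local_name(predicate: str) -> str:
    # Alignment-format files exist with and without '#' after the
    # namespace; match on the trailing local name.
    for name in ("entity1", "entity2", "measure", "relation", "onto1", "onto2"):
        if predicate == ALIGNMENT_NS + name or predicate.endswith("#" + name):
            return name
    return ""


def read_alignment_rdf(path) -> Alignment:
    """Read the Alignment-format RDF (Cell elements with entity1,
    entity2, measure, relation)."""
    graph = Graph()
    try:
        graph.parse(str(path), format="xml")
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as RDF/XML: {exc}") from exc

    cells: dict = {}
    onto = {"onto1": "", "onto2": ""}
    for subject, predicate, obj in graph:
        name = _local_name(str(predicate))
        if name in ("onto1", "onto2"):
            onto[name] = str(obj)
        elif name:
            cells.setdefault(subject, {})[name] = str(obj)

    mappings = []
    for index, (subject, fields) in enumerate(
        sorted(cells.items(), key=lambda kv: str(kv[0]))
    ):
        if "entity1" not in fields or "entity2" not in fields:
            raise FormatError(
                f"{path}: cell {index} is missing entity1 or entity2"
            )
        symbol = fields.get("relation", "=")
        if symbol not in _SYMBOL_TO_RELATION:
            raise FormatError(
                f"{path}: cell {index} has unknown relation {symbol!r}"
            )
        try:
            confidence = float(fields.get("measure", "1.0"))
        except ValueError as exc:
            raise FormatError(
                f"{path}: cell {index} has non-numeric measure"
            ) from exc
        mappings.append(
            Mapping(
                source_iri=fields["entity1"],
                target_iri=fields["entity2"],
                relation=_SYMBOL_TO_RELATION[symbol],
                confidence=confidence,
            )
        )
    return Alignment(onto["onto1"], onto["onto2"], mappings)


def write_alignment_rdf(alignment: Alignment, path) -> None:
    """Write the Alignment-format RDF with one Cell per mapping, in
    deterministic (source, target) order — byte-identical across runs."""
    lines = [
        "<?xml version='1.0' encoding='utf-8'?>",
        f"<rdf:RDF xmlns='{ALIGNMENT_NS}'",
        "         xmlns:rdf='http://www.w3.org/1999/02/22-rdf-syntax-ns#'",
        "         xmlns:xsd='http://www.w3.org/2001/XMLSchema#'>",
        "<Alignment>",
        "  <xml>yes</xml>",
        "  <level>0</level>",
        "  <type>??</type>",
        f"  <onto1>{escape(alignment.source_ontology_id)}</onto1>",
        f"  <onto2>{escape(alignment.target_ontology_id)}</onto2>",
    ]
    for mapping in alignment.sorted_mappings():
        lines += [
            "  <map>",
            "    <Cell>",
            f"      <entity1 rdf:resource={quoteattr(mapping.source_iri)}/>",
            f"      <entity2 rdf:resource={quoteattr(mapping.target_iri)}/>",
            f"      <measure rdf:datatype='http://www.w3.org/2001/XMLSchema#float'>"
            f"{mapping.confidence!r}</measure>",
            f"      <relation>{escape(_RELATION_TO_SYMBOL[mapping.relation])}"
            "</relation>",
            "    </Cell>",
            "  </map>",
        ]
    lines += ["</Alignment>", "</rdf:RDF>", ""]
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\n".join(lines))


TSV_ALIGNMENT_COLUMNS = ("source_iri", "target_iri", "relation", "confidence")


def read_alignment_tsv(
    path, source_ontology_id: str = "", target_ontology_id: str = ""
) -> Alignment:
    """Read the TSV alignment dialect (source_iri, target_iri, relation,
    confidence)."""
    mappings = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != TSV_ALIGNMENT_COLUMNS:
            raise FormatError(
                f"{path}: expected header {TSV_ALIGNMENT_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            mappings.append(
                Mapping(
                    source_iri=row["source_iri"],
                    target_iri=row["target_iri"],
                    relation=row["relation"],
                    confidence=float(row["confidence"]),
                )
            )
    return Alignment(source_ontology_id, target_ontology_id, mappings)


def write_alignment_tsv(alignment: Alignment, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_ALIGNMENT_COLUMNS)
        for mapping in alignment.sorted_mappings():
            writer.writerow(
                [
                    mapping.source_iri,
                    mapping.target_iri,
                    mapping.relation,
                    repr(mapping.confidence),
                ]
            )


def normalize(alignment: Alignment, pair_order: Sequence[str]) -> Alignment:
    """Canonicalize an alignment for one ontology pair.

    Matching A to B is equivalent to matching B to A, so mappings are
    reoriented to put ``pair_order[0]``'s classes on the source side.
    Non-equivalence mappings are dropped (with a logged count) and
    cross-orientation duplicates collapse keeping the maximum confidence.
    Idempotent.
    """
    order = tuple(pair_order)
    if len(order) != 2 or order[0] == order[1]:
        raise UsageError("pair_order must name two distinct ontology ids")
    declared = {alignment.source_ontology_id, alignment.target_ontology_id}
    if declared != set(order):
        raise ValidationError(
            f"alignment is between {sorted(declared)}, not {sorted(order)}"
        )
    flip = alignment.source_ontology_id != order[0]

    result = Alignment(
        order[0], order[1], provenance=alignment.provenance
    )
    dropped = 0
    for mapping in alignment.mappings:
        oriented = mapping.invert() if flip else mapping
        if oriented.relation != EQUIVALENCE:
            dropped += 1
            continue
        result.add(oriented)
    if dropped:
        logger.info(
            "normalize(%s): dropped %d non-equivalence mapping(s)",
            alignment.provenance or "alignment",
            dropped,
        )
    return result


def consensus(alignments: Sequence[Alignment], min_votes: int) -> Alignment:
    """Vote-based consensus: keep the mappings selected by at least
    ``min_votes`` of the input alignments.

    Inputs must already be normalized to the same pair order.  The
    consensus confidence is the vote fraction (votes / number of
    systems).
    """
    if not alignments:
        raise UsageError("consensus requires at least one alignment")
    if not 1 <= min_votes <= len(alignments):
        raise UsageError(
            f"min_votes must be in [1, {len(alignments)}], got {min_votes}"
        )
    order = (alignments[0].source_ontology_id, alignments[0].target_ontology_id)
    for alignment in alignments:
        if (alignment.source_ontology_id, alignment.target_ontology_id) != order:
            raise ValidationError(
                "all alignments must be normalized to the same pair order"
            )
    votes: dict[tuple[str, str], int] = {}
    for alignment in alignments:
        for pair in alignment.pairs():
            votes[pair] = votes.get(pair, 0) + 1
    result = Alignment(
        order[0], order[1], provenance=f"consensus(vote>={min_votes})"
    )
    for (source, target), count in votes.items():
        if count >= min_votes:
            result.add(
                Mapping(
                    source_iri=source,
                    target_iri=target,
                    relation=EQUIVALENCE,
                    confidence=count / len(alignments),
                )
            )
    return result
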