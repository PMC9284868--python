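"""Lightweight ontology model: a rooted DAG of named classes.

The model keeps exactly what the downstream evaluation needs — the
subsumption (is-a) hierarchy between named classes, preferred labels,
synonyms and UMLS concept unique identifier (CUI) annotations.  Object
properties, class expressions and non-subsumption axioms are deliberately
out of scope: every analysis in this toolkit consumes only the class DAG.

Two on-disk representations are supported: OWL in RDF/XML serialization
(read via rdflib) and a plain TSV dialect used for fixtures and diffable
intermediate files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL, SKOS

from .errors import FormatError, UsageError, ValidationError

#: Default annotation properties scanned for synonyms by the OWL reader.
DEFAULT_SYNONYM_PROPERTIES = (
    str(SKOS.altLabel),
    "http://www.geneontology.org/formats/oboInOwl#hasExactSynonym",
)

#: Root IRI synthesized when an OWL file has several parentless classes.
SYNTHETIC_ROOT_IRI = str(OWL.Thing)

_OBO_IN_OWL = Namespace("http://www.geneontology.org/formats/oboInOwl#")

TSV_COLUMNS = ("iri", "parent_iris", "label", "synonyms", "cuis")


@dataclass
class OntologyClass:
    """A named class: identifier, lexical annotations and CUI codes."""

    iri: str
    preferred_label: str = ""
    synonyms: frozenset[str] = frozenset()
    parent_iris: frozenset[str] = frozenset()
    cuis: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.iri:
            raise ValidationError("class iri must be non-empty")
        self.synonyms = frozenset(self.synonyms)
        self.parent_iris = frozenset(self.parent_iris)
        self.cuis = frozenset(self.cuis)
        if self.iri in self.parent_iris:
            raise ValidationError(f"class {self.iri!r} lists itself as parent")


@dataclass
class Ontology:
    """A rooted, acyclic class hierarchy.

    ``classes`` maps IRI to :class:`OntologyClass`; ``root_iri`` names the
    single root.  Multiple inheritance is allowed (the hierarchy is a DAG,
    not a tree).  Construction validates acyclicity, the uniqueness of the
    root and that every class reaches the root through parent edges.
    """

    ontology_id: str
    classes: dict[str, OntologyClass]
    root_iri: str
    _children: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._validate()
        self._children = {iri: set() for iri in self.classes}
        for cls in self.classes.values():
            for parent in cls.parent_iris:
                self._children[parent].add(cls.iri)

    def _validate(self) -> None:
        if not self.classes:
            raise ValidationError("ontology must contain at least one class")
        if self.root_iri not in self.classes:
            raise ValidationError(f"root {self.root_iri!r} not among classes")
        if self.classes[self.root_iri].parent_iris:
            raise ValidationError("root class must not have parents")
        graph = nx.DiGraph()
        graph.add_nodes_from(self.classes)
        for cls in self.classes.values():
            for parent in cls.parent_iris:
                if parent not in self.classes:
                    raise ValidationError(
                        f"class {cls.iri!r} has unknown parent {parent!r}"
                    )
                graph.add_edge(cls.iri, parent)
        if not nx.is_directed_acyclic_graph(graph):
            member = nx.find_cycle(graph)[0][0]
            raise ValidationError(
                f"subclass graph contains a cycle through {member!r}"
            )
        for iri, cls in self.classes.items():
            if iri != self.root_iri and not cls.parent_iris:
                raise ValidationError(
                    f"class {iri!r} is parentless but is not the root"
                )

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, iri: str) -> bool:
        return iri in self.classes

    def children(self, iri: str) -> set[str]:
        if iri not in self.classes:
            raise KeyError(iri)
        return set(self._children[iri])


def _closure(start: str, neighbours) -> set[str]:
    seen: set[str] = set()
    frontier = list(neighbours(start))
    while frontier:
        node = frontier.pop()
        if node not in seen:
            seen.add(node)
            frontier.extend(neighbours(node))
    return seen


def ancestors(ontology: Ontology, iri: str) -> set[str]:
    """Strict ancestors of ``iri``: the transitive closure over parent
    edges, excluding ``iri`` itself.  Includes the root for any non-root
    class."""
    if iri not in ontology.classes:
        raise KeyError(f"unknown class {iri!r}")
    return _closure(iri, lambda n: ontology.classes[n].parent_iris)


def descendants(ontology: Ontology, iri: str) -> set[str]:
    """Strict descendants of ``iri`` via reversed parent edges."""
    if iri not in ontology.classes:
        raise KeyError(f"unknown class {iri!r}")
    return _closure(iri, lambda n: ontology._children[n])


def top_level_classes(ontology: Ontology) -> set[str]:
    """The direct children of the root — the ontology's categories."""
    return ontology.children(ontology.root_iri)


def top_level_ancestors(ontology: Ontology, iri: str) -> set[str]:
    """The top-level classes a class falls under.

    A top-level class is its own top-level ancestor.  Never empty for a
    non-root class of a valid ontology; the root itself has no top-level
    ancestor and is rejected.
    """
    if iri == ontology.root_iri:
        raise UsageError("the root has no top-level ancestor")
    result = ({iri} | ancestors(ontology, iri)) & top_level_classes(ontology)
    return result


def build_ontology(
    ontology_id: str,
    classes: Iterable[OntologyClass],
    *,
    root_iri: str | None = None,
    synthetic_root_iri: str = SYNTHETIC_ROOT_IRI,
) -> Ontology:
    """Assemble an :class:`Ontology` from loose classes.

    If ``root_iri`` is None the root is inferred: a single parentless
    class becomes the root; with several parentless classes a synthetic
    root is created and they are attached to it.
    """
    class_map: dict[str, OntologyClass] = {}
    for cls in classes:
        if cls.iri in class_map:
            raise ValidationError(f"duplicate class iri {cls.iri!r}")
        class_map[cls.iri] = cls

    if root_iri is None:
        parentless = sorted(
            iri for iri, c in class_map.items() if not c.parent_iris
        )
        if not parentless:
            raise ValidationError("no parentless class to use as root")
        if len(parentless) == 1:
            root_iri = parentless[0]
        else:
            root_iri = synthetic_root_iri
            if root_iri in class_map:
                raise ValidationError(
                    f"synthetic root {root_iri!r} collides with a class"
                )
            class_map[root_iri] = OntologyClass(iri=root_iri)
            for iri in parentless:
                old = class_map[iri]
                class_map[iri] = OntologyClass(
                    iri=old.iri,
                    preferred_label=old.preferred_label,
                    synonyms=old.synonyms,
                    parent_iris=frozenset({root_iri}),
                    cuis=old.cuis,
                )
    return Ontology(ontology_id=ontology_id, classes=class_map, root_iri=root_iri)


def load_ontology_owl(
    path,
    cui_property_iris: Sequence[str] = (),
    *,
    ontology_id: str | None = None,
    synonym_property_iris: Sequence[str] = DEFAULT_SYNONYM_PROPERTIES,
) -> Ontology:
    """Read an RDF/XML OWL file into an :class:`Ontology`.

    Only named classes are modeled.  Subclass edges come from
    ``rdfs:subClassOf`` triples between named classes; labels from
    ``rdfs:label``; synonyms and CUI codes from the configured annotation
    properties.  Anonymous superclasses (restrictions etc.) are ignored.
    Classes without an asserted named parent are attached to the root.
    """
    graph = Graph()
    try:
        graph.parse(str(path), format="xml")
    except Exception as exc:  # rdflib raises many parser-specific types
        raise FormatError(f"cannot parse {path} as RDF/XML: {exc}") from exc

    named = {
        str(s)
        for s in graph.subjects(RDF.type, OWL.Class)
        if isinstance(s, URIRef) and str(s) != str(OWL.Thing)
    }
    if not named:
        raise FormatError(f"{path} declares no named owl:Class")

    syn_props = [URIRef(p) for p in synonym_property_iris]
    cui_props = [URIRef(p) for p in cui_property_iris]

    classes = []
    for iri in sorted(named):
        ref = URIRef(iri)
        parents = {
            str(o)
            for o in graph.objects(ref, RDFS.subClassOf)
            if isinstance(o, URIRef) and str(o) in named
        }
        label = next(
            (str(o) for o in graph.objects(ref, RDFS.label)), ""
        )
        synonyms = {
            str(o) for p in syn_props for o in graph.objects(ref, p)
        }
        cuis = {str(o) for p in cui_props for o in graph.objects(ref, p)}
        classes.append(
            OntologyClass(
                iri=iri,
                preferred_label=label,
                synonyms=frozenset(synonyms),
                parent_iris=frozenset(parents),
                cuis=frozenset(cuis),
            )
        )
    oid = ontology_id if ontology_id is not None else str(path)
    return build_ontology(oid, classes)


#: Annotation property used by the OWL writer for CUI codes; mirrors the
#: UMLS_CUI property dialect used by ORDO-style ontologies.
CUI_ANNOTATION_PROPERTY = "http://www.example.org/annotations#UMLS_CUI"


def write_ontology_owl(
    ontology: Ontology,
    path,
    *,
    cui_property_iri: str = CUI_ANNOTATION_PROPERTY,
    synonym_property_iri: str = DEFAULT_SYNONYM_PROPERTIES[0],
) -> None:
    """Serialize an ontology as RDF/XML OWL (inverse of the reader)."""
    graph = Graph()
    graph.bind("owl", OWL)
    graph.bind("skos", SKOS)
    cui_prop = URIRef(cui_property_iri)
    syn_prop = URIRef(synonym_property_iri)
    for iri in sorted(ontology.classes):
        cls = ontology.classes[iri]
        ref = URIRef(iri)
        graph.add((ref, RDF.type, OWL.Class))
        for parent in sorted(cls.parent_iris):
            graph.add((ref, RDFS.subClassOf, URIRef(parent)))
        if cls.preferred_label:
            graph.add((ref, RDFS.label, Literal(cls.preferred_label)))
        for syn in sorted(cls.synonyms):
            graph.add((ref, syn_prop, Literal(syn)))
        for cui in sorted(cls.cuis):
            graph.add((ref, cui_prop, Literal(cui)))
    graph.serialize(destination=str(path), format="xml")


def _split(cell: str) -> frozenset[str]:
    return frozenset(part for part in cell.split("|") if part)


def load_ontology_tsv(path, *, ontology_id: str | None = None) -> Ontology:
    """Read the TSV hierarchy dialect.

    Columns: ``iri``, ``parent_iris`` (pipe-separated), ``label``,
    ``synonyms`` (pipe-separated), ``cuis`` (pipe-separated); header row
    mandatory; exactly one row with empty ``parent_iris`` (the root).
    """
    classes: list[OntologyClass] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != TSV_COLUMNS:
            raise FormatError(
                f"{path}: expected header {TSV_COLUMNS}, got {reader.fieldnames}"
            )
        for row in reader:
            classes.append(
                OntologyClass(
                    iri=row["iri"],
                    preferred_label=row["label"],
                    synonyms=_split(row["synonyms"]),
                    parent_iris=_split(row["parent_iris"]),
                    cuis=_split(row["cuis"]),
                )
            )
    roots = [c for c in classes if not c.parent_iris]
    if len(roots) != 1:
        raise ValidationError(
            f"{path}: expected exactly one parentless row, found {len(roots)}"
        )
    oid = ontology_id if ontology_id is not None else str(path)
    return build_ontology(oid, classes, root_iri=roots[0].iri)


def write_ontology_tsv(ontology: Ontology, path) -> None:
    """Write the TSV hierarchy dialect, rows sorted by IRI."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for iri in sorted(ontology.classes):
            cls = ontology.classes[iri]
            writer.writerow(
                [
                    cls.iri,
                    "|".join(sorted(cls.parent_iris)),
                    cls.preferred_label,
                    "|".join(sorted(cls.synonyms)),
                    "|".join(sorted(cls.cuis)),
                ]
            )
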