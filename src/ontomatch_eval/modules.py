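"""Seed-signature module extraction over the class hierarchy.

A module is a subset of an ontology built around a seed signature (a list
of classes of interest).  Three strategies are supported: a *top* module
keeps the seed plus all its subclasses, a *bottom* module keeps the seed
plus all its superclasses, and a *star* module is the intersection of the
two.  Extraction operates purely on the subclass DAG; it makes no
logical-locality guarantees.  The root is always retained so that the
module's top-level hierarchy stays well defined, and retained classes cut
off from their parents are re-attached to the root.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UsageError, ValidationError
from .ontology import Ontology, OntologyClass, ancestors, descendants

MODULE_MODES = ("top", "bottom", "star")


@dataclass(frozen=True)
class SeedSignature:
    """A non-empty set of class IRIs from one ontology."""

    class_iris: frozenset[str]
    ontology_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_iris", frozenset(self.class_iris))
        if not self.class_iris:
            raise ValidationError("seed signature must be non-empty")


def _check_seed(ontology: Ontology, seed: SeedSignature) -> None:
    missing = seed.class_iris - ontology.classes.keys()
    if missing:
        raise ValidationError(
            f"seed classes not in ontology: {sorted(missing)[:5]}"
        )


def extend_seed_with_ancestors(
    ontology: Ontology, seed: SeedSignature
) -> SeedSignature:
    """Close a seed under ancestors, so the module spans the full
    top-level hierarchy above every seed class.  Idempotent; the result
    always contains the root."""
    _check_seed(ontology, seed)
    extended = set(seed.class_iris)
    for iri in seed.class_iris:
        extended |= ancestors(ontology, iri)
    return SeedSignature(frozenset(extended), seed.ontology_id)


def extract_module(
    ontology: Ontology, seed: SeedSignature, mode: str
) -> Ontology:
    """Extract a top, bottom or star module as a new valid ontology.

    The returned ontology keeps only parent edges between retained
    classes and is re-rooted at the original root (always retained).
    """
    if mode not in MODULE_MODES:
        raise UsageError(f"mode must be one of {MODULE_MODES}, got {mode!r}")
    _check_seed(ontology, seed)

    def expand(direction) -> set[str]:
        out = set(seed.class_iris)
        for iri in seed.class_iris:
            out |= direction(ontology, iri)
        return out

    if mode == "top":
        retained = expand(descendants)
    elif mode == "bottom":
        retained = expand(ancestors)
    else:
        retained = expand(descendants) & expand(ancestors)
    retained.add(ontology.root_iri)

    root = ontology.root_iri
    classes = []
    for iri in retained:
        cls = ontology.classes[iri]
        parents = cls.parent_iris & retained
        if not parents and iri != root:
            parents = frozenset({root})
        classes.append(
            OntologyClass(
                iri=cls.iri,
                preferred_label=cls.preferred_label,
                synonyms=cls.synonyms,
                parent_iris=frozenset(parents),
                cuis=cls.cuis,
            )
        )
    return Ontology(
        ontology_id=ontology.ontology_id,
        classes={c.iri: c for c in classes},
        root_iri=root,
    )


@dataclass(frozen=True)
class ModuleStats:
    ontology_id: str
    total_classes: int
    module_classes: int
    percent: float  # raw, 100 * module / total
    percent_label: str  # nearest integer; one decimal when < 1%


def format_percent(value: float) -> str:
    """Nearest-integer percent label, one decimal below 1%, ties away
    from zero (prints '2%' for 2.06, '0.4%' for 0.399...)."""
    from .reporting import round_half_away

    if 0 < value < 1:
        return f"{round_half_away(value, 1)}%"
    return f"{int(round_half_away(value, 0))}%"


def module_stats(ontology: Ontology, module: Ontology) -> ModuleStats:
    """Size summary of a module relative to its parent ontology."""
    extra = module.classes.keys() - ontology.classes.keys()
    if extra:
        raise ValidationError(
            f"module contains classes absent from ontology: {sorted(extra)[:5]}"
        )
    percent = 100.0 * len(module) / len(ontology)
    return ModuleStats(
        ontology_id=ontology.ontology_id,
        total_classes=len(ontology),
        module_classes=len(module),
        percent=percent,
        percent_label=format_percent(percent),
    )
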