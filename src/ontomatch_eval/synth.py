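"""Synthetic ontology-pair scenarios for exercising the full pipeline.

Licensed terminologies (SNOMED CT, the UMLS) cannot ship with a test
suite, so this module generates scenarios with the same statistical
structure: two rooted class DAGs with a small set of top-level
categories, a subset of categories manually "matched" across the pair, a
population of shared concepts appearing once per ontology under paired
categories, per-class CUI annotations that induce an (incomplete)
reference alignment, and simulated matcher outputs containing planted
correct mappings, incorrect same-category mappings (invisible to the
top-level-hierarchy filter) and incorrect cross-category mappings (which
the filter should flag).

All generators are pure functions of (config, seed): the same inputs
reproduce the same scenario element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .alignments import Alignment, Mapping, write_alignment_rdf, write_alignment_tsv
from .errors import UsageError
from .evaluation import CuiAnnotationTable, write_cui_table_tsv
from .hierarchy import TopLevelMappingSet, write_top_level_mappings
from .ontology import (
    Ontology,
    OntologyClass,
    build_ontology,
    top_level_ancestors,
    write_ontology_owl,
    write_ontology_tsv,
)
from .reporting import round_half_away


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the scenario generator.

    Defaults mirror the shape of real biomedical terminology pairs at
    desk scale: 19 top-level categories per ontology (the SNOMED CT /
    NCIt count), roughly two thirds of the categories semantically
    matched across the pair, moderate concept sharing, an incomplete CUI
    silver standard, and a matcher that finds about two thirds of the
    true mappings while planting false ones, half of which cross
    category boundaries.
    """

    seed: int = 0
    n_categories_a: int = 19
    n_categories_b: int = 19
    category_map_fraction: float = 13 / 19
    classes_per_category: int = 40
    max_depth: int = 5
    shared_concept_fraction: float = 0.4
    cui_coverage: float = 0.8
    matcher_recall: float = 0.66
    n_false_mappings: int = 200
    cross_category_fraction: float = 0.5
    #: extra child->parent edges per ontology, to exercise multiple
    #: inheritance (possibly across categories)
    extra_parent_edges: int = 5

    def __post_init__(self) -> None:
        for name in (
            "category_map_fraction",
            "shared_concept_fraction",
            "cui_coverage",
            "matcher_recall",
            "cross_category_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise UsageError(f"{name} must lie in [0, 1], got {value}")
        for name in ("n_categories_a", "n_categories_b", "classes_per_category", "max_depth"):
            if getattr(self, name) < 1:
                raise UsageError(f"{name} must be positive")
        if self.n_false_mappings < 0 or self.extra_parent_edges < 0:
            raise UsageError("counts must be non-negative")


@dataclass(frozen=True)
class Scenario:
    """One generated ontology pair with its ground truth."""

    ontology_a: Ontology
    ontology_b: Ontology
    ground_truth: Alignment
    cui_table_a: CuiAnnotationTable
    cui_table_b: CuiAnnotationTable
    top_level_mappings: TopLevelMappingSet


def _iri(oid: str, local: str) -> str:
    return f"http://purl.example.org/{oid}#{local}"


def _build_side(
    oid: str,
    n_categories: int,
    n_matched: int,
    n_shared: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    label_for_concept,
) -> tuple[Ontology, dict[str, int], list[list[str]]]:
    """Build one ontology: a root, category subtrees, and per matched
    category the slots that will host shared concepts.

    Returns the ontology, a concept-id map (class iri -> global concept
    id for shared classes) and per-category class lists.
    """
    root = _iri(oid, "Root")
    classes: dict[str, OntologyClass] = {
        root: OntologyClass(iri=root, preferred_label=f"{oid} root")
    }
    per_category: list[list[str]] = []
    depth = {root: 0}
    concept_of: dict[str, int] = {}

    concept_counter = 0
    for cat in range(n_categories):
        cat_iri = _iri(oid, f"T{cat}")
        classes[cat_iri] = OntologyClass(
            iri=cat_iri,
            preferred_label=f"{oid} category {cat}",
            parent_iris=frozenset({root}),
        )
        depth[cat_iri] = 1
        members = [cat_iri]
        shared_here = n_shared if cat < n_matched else 0
        for j in range(config.classes_per_category):
            iri = _iri(oid, f"T{cat}_C{j}")
            candidates = [m for m in members if depth[m] < config.max_depth]
            parent = candidates[int(rng.integers(len(candidates)))]
            if j < shared_here:
                # shared concept: same global id on both sides of the pair
                gid = cat * config.classes_per_category + j
                concept_of[iri] = gid
                label = label_for_concept(gid, oid)
            else:
                concept_counter += 1
                label = f"{oid} concept {cat}.{j}"
            classes[iri] = OntologyClass(
                iri=iri,
                preferred_label=label,
                parent_iris=frozenset({parent}),
            )
            depth[iri] = depth[parent] + 1
            members.append(iri)
        per_category.append(members)

    ontology = build_ontology(oid, classes.values(), root_iri=root)
    ontology = _add_extra_edges(ontology, config.extra_parent_edges, rng)
    return ontology, concept_of, per_category


def _add_extra_edges(
    ontology: Ontology, n_edges: int, rng: np.random.Generator
) -> Ontology:
    """Add random multi-parent edges while keeping the DAG acyclic."""
    from .ontology import ancestors as _ancestors

    if n_edges == 0:
        return ontology
    iris = sorted(
        iri
        for iri in ontology.classes
        if iri != ontology.root_iri
        and ontology.root_iri not in ontology.classes[iri].parent_iris
    )
    classes = {iri: cls for iri, cls in ontology.classes.items()}
    added = 0
    attempts = 0
    while added < n_edges and attempts < 50 * (n_edges + 1):
        attempts += 1
        child = iris[int(rng.integers(len(iris)))]
        parent = iris[int(rng.integers(len(iris)))]
        if parent == child or parent in classes[child].parent_iris:
            continue
        # rebuild a probe ontology lazily is costly; check acyclicity by
        # ensuring the child is not an ancestor of the candidate parent
        probe = Ontology(
            ontology_id=ontology.ontology_id,
            classes=classes,
            root_iri=ontology.root_iri,
        )
        if child in _ancestors(probe, parent):
            continue
        old = classes[child]
        classes[child] = OntologyClass(
            iri=old.iri,
            preferred_label=old.preferred_label,
            synonyms=old.synonyms,
            parent_iris=old.parent_iris | {parent},
            cuis=old.cuis,
        )
        added += 1
    return Ontology(
        ontology_id=ontology.ontology_id, classes=classes, root_iri=ontology.root_iri
    )


def generate_scenario(config: SyntheticConfig) -> Scenario:
    """Generate a full scenario: two ontologies, the ground-truth
    equivalence alignment over shared concepts, CUI tables covering a
    ``cui_coverage`` fraction of the ground truth, and the matched
    top-level category table."""
    rng = np.random.default_rng(config.seed)
    n_matched = int(
        round_half_away(
            config.category_map_fraction
            * min(config.n_categories_a, config.n_categories_b)
        )
    )
    n_shared = int(
        round_half_away(config.shared_concept_fraction * config.classes_per_category)
    )
    if n_matched == 0 and n_shared > 0:
        raise UsageError(
            "shared concepts require at least one matched category pair "
            "(category_map_fraction too small)"
        )

    def label_for_concept(gid: int, oid: str) -> str:
        # lexical near-duplicates across the pair: same words, different
        # casing, mimicking 'Aneurysmal Bone Cyst' vs 'Aneurysmal bone cyst'
        base = f"Shared Concept {gid}"
        return base if oid.endswith("A") else base.lower().capitalize()

    onto_a, concepts_a, _ = _build_side(
        "SYNTH-A", config.n_categories_a, n_matched, n_shared, config, rng,
        label_for_concept,
    )
    onto_b, concepts_b, _ = _build_side(
        "SYNTH-B", config.n_categories_b, n_matched, n_shared, config, rng,
        label_for_concept,
    )

    by_gid_a = {gid: iri for iri, gid in concepts_a.items()}
    by_gid_b = {gid: iri for iri, gid in concepts_b.items()}
    shared_gids = sorted(by_gid_a.keys() & by_gid_b.keys())

    ground_truth = Alignment(
        "SYNTH-A", "SYNTH-B", provenance="ground-truth"
    )
    cui_map_a: dict[str, frozenset[str]] = {}
    cui_map_b: dict[str, frozenset[str]] = {}
    for gid in shared_gids:
        iri_a, iri_b = by_gid_a[gid], by_gid_b[gid]
        ground_truth.add(Mapping(source_iri=iri_a, target_iri=iri_b))
        if rng.random() < config.cui_coverage:
            cui = f"C{1000000 + gid}"
            cui_map_a[iri_a] = frozenset({cui})
            cui_map_b[iri_b] = frozenset({cui})

    tlms = TopLevelMappingSet(
        pair=("SYNTH-A", "SYNTH-B"),
        pairs=frozenset(
            (_iri("SYNTH-A", f"T{i}"), _iri("SYNTH-B", f"T{i}"))
            for i in range(n_matched)
        ),
    )
    return Scenario(
        ontology_a=onto_a,
        ontology_b=onto_b,
        ground_truth=ground_truth,
        cui_table_a=CuiAnnotationTable("SYNTH-A", cui_map_a),
        cui_table_b=CuiAnnotationTable("SYNTH-B", cui_map_b),
        top_level_mappings=tlms,
    )


def degrade_reference(
    ground_truth: Alignment, completeness: float, seed: int
) -> Alignment:
    """Emulate an incomplete reference: keep each mapping independently
    with probability ``completeness``."""
    if not 0.0 <= completeness <= 1.0:
        raise UsageError("completeness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kept = [
        m
        for m in ground_truth.sorted_mappings()
        if rng.random() < completeness
    ]
    return Alignment(
        ground_truth.source_ontology_id,
        ground_truth.target_ontology_id,
        kept,
        provenance=f"{ground_truth.provenance}(completeness={completeness})",
    )


#: planting labels attached to simulated mappings
PLANTED_TRUE = "true"
PLANTED_FALSE_WITHIN = "false_within_category"
PLANTED_FALSE_CROSS = "false_cross_category"


@dataclass(frozen=True)
class SimulatedMatcherOutput:
    """A simulated matcher alignment plus the planting label of every
    mapping, keyed by (source, target) pair."""

    alignment: Alignment
    labels: dict[tuple[str, str], str]


def simulate_matcher(
    scenario: Scenario, config: SyntheticConfig, seed: int
) -> SimulatedMatcherOutput:
    """Simulate one matcher at the error-rate level.

    Each ground-truth mapping is recovered with probability
    ``matcher_recall``.  Exactly ``n_false_mappings`` false pairs are
    planted: a ``cross_category_fraction`` share (an exact count, rounded
    half up) joins classes under category pairs NOT in the top-level
    mapping table — detectable by the hierarchy filter — and the rest
    joins wrong classes under matched categories, invisible to it.
    """
    rng = np.random.default_rng(seed)
    gt_pairs = scenario.ground_truth.pairs()
    alignment = Alignment("SYNTH-A", "SYNTH-B", provenance="simulated-matcher")
    labels: dict[tuple[str, str], str] = {}

    for mapping in scenario.ground_truth.sorted_mappings():
        if rng.random() < config.matcher_recall:
            alignment.add(mapping)
            labels[mapping.pair] = PLANTED_TRUE

    n_cross = int(round_half_away(config.cross_category_fraction * config.n_false_mappings))
    n_within = config.n_false_mappings - n_cross

    tlms_pairs = scenario.top_level_mappings.pairs
    onto_a, onto_b = scenario.ontology_a, scenario.ontology_b
    pool_a = sorted(iri for iri in onto_a.classes if iri != onto_a.root_iri)
    pool_b = sorted(iri for iri in onto_b.classes if iri != onto_b.root_iri)
    tops_a = {iri: top_level_ancestors(onto_a, iri) for iri in pool_a}
    tops_b = {iri: top_level_ancestors(onto_b, iri) for iri in pool_b}

    def plant(count: int, want_consistent: bool, label: str) -> None:
        planted = 0
        attempts = 0
        limit = 500 * (count + 1)
        while planted < count:
            attempts += 1
            if attempts > limit:
                raise UsageError(
                    f"could not find {count} candidate false pairs "
                    f"({label}); enlarge the scenario"
                )
            iri_a = pool_a[int(rng.integers(len(pool_a)))]
            iri_b = pool_b[int(rng.integers(len(pool_b)))]
            pair = (iri_a, iri_b)
            if pair in gt_pairs or pair in labels:
                continue
            consistent = any(
                (ta, tb) in tlms_pairs
                for ta in tops_a[iri_a]
                for tb in tops_b[iri_b]
            )
            if consistent != want_consistent:
                continue
            alignment.add(Mapping(source_iri=iri_a, target_iri=iri_b))
            labels[pair] = label
            planted += 1

    plant(n_cross, want_consistent=False, label=PLANTED_FALSE_CROSS)
    plant(n_within, want_consistent=True, label=PLANTED_FALSE_WITHIN)
    return SimulatedMatcherOutput(alignment=alignment, labels=labels)


def simulate_matchers(
    scenario: Scenario, config: SyntheticConfig, seed: int, n_matchers: int = 3
) -> list[SimulatedMatcherOutput]:
    """Independent simulated matchers (distinct sub-seeds)."""
    return [
        simulate_matcher(scenario, config, seed=seed * 1000 + i)
        for i in range(n_matchers)
    ]


def write_scenario(scenario: Scenario, outdir) -> dict[str, Path]:
    """Emit the scenario in the toolkit's file dialects under ``outdir``.

    Writes each ontology as both TSV and OWL (RDF/XML), the ground truth
    as Alignment-format RDF and TSV, the CUI tables and the top-level
    mapping table.  Returns the path of every written file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology_a_tsv": outdir / "ontology_a.tsv",
        "ontology_a_owl": outdir / "ontology_a.owl",
        "ontology_b_tsv": outdir / "ontology_b.tsv",
        "ontology_b_owl": outdir / "ontology_b.owl",
        "ground_truth_rdf": outdir / "ground_truth.rdf",
        "ground_truth_tsv": outdir / "ground_truth.tsv",
        "cui_table_a": outdir / "cui_a.tsv",
        "cui_table_b": outdir / "cui_b.tsv",
        "top_level_mappings": outdir / "top_level_mappings.tsv",
    }
    write_ontology_tsv(scenario.ontology_a, paths["ontology_a_tsv"])
    write_ontology_owl(scenario.ontology_a, paths["ontology_a_owl"])
    write_ontology_tsv(scenario.ontology_b, paths["ontology_b_tsv"])
    write_ontology_owl(scenario.ontology_b, paths["ontology_b_owl"])
    write_alignment_rdf(scenario.ground_truth, paths["ground_truth_rdf"])
    write_alignment_tsv(scenario.ground_truth, paths["ground_truth_tsv"])
    write_cui_table_tsv(scenario.cui_table_a, paths["cui_table_a"])
    write_cui_table_tsv(scenario.cui_table_b, paths["cui_table_b"])
    write_top_level_mappings(scenario.top_level_mappings, paths["top_level_mappings"])
    return paths
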