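"""Shared fixtures: tiny hand-built hierarchies, random DAG generators
and brute-force oracles the unit tests compare against."""

from __future__ import annotations

import numpy as np
import pytest

from ontomatch_eval import (
    Alignment,
    Mapping,
    Ontology,
    OntologyClass,
    SyntheticConfig,
    generate_scenario,
)


def make_ontology(edges: dict[str, set[str]], ontology_id: str = "T") -> Ontology:
    """Build an ontology from an iri -> parents mapping ('' parents = root)."""
    classes = {
        iri: OntologyClass(iri=iri, parent_iris=frozenset(parents))
        for iri, parents in edges.items()
    }
    roots = [iri for iri, parents in edges.items() if not parents]
    assert len(roots) == 1
    return Ontology(ontology_id=ontology_id, classes=classes, root_iri=roots[0])


@pytest.fixture
def chain():
    """root <- a <- b <- c (c is the deepest)."""
    return make_ontology(
        {"root": set(), "a": {"root"}, "b": {"a"}, "c": {"b"}}
    )


@pytest.fixture
def diamond():
    """d under both b and c, which share parent a under root."""
    return make_ontology(
        {
            "root": set(),
            "a": {"root"},
            "b": {"a"},
            "c": {"a"},
            "d": {"b", "c"},
        }
    )


def random_dag(rng: np.random.Generator, n_nodes: int) -> Ontology:
    """A random rooted DAG: node i picks 1-2 parents among nodes < i."""
    edges: dict[str, set[str]] = {"n0": set()}
    for i in range(1, n_nodes):
        n_parents = 1 + int(rng.integers(2)) if i > 1 else 1
        parents = {
            f"n{int(p)}" for p in rng.choice(i, size=min(n_parents, i), replace=False)
        }
        edges[f"n{i}"] = parents
    return make_ontology(edges)


def reachable_oracle(ontology: Ontology) -> dict[str, set[str]]:
    """Brute-force ancestor sets by iterated expansion until fixpoint."""
    reach = {
        iri: set(cls.parent_iris) for iri, cls in ontology.classes.items()
    }
    changed = True
    while changed:
        changed = False
        for iri in reach:
            new = set(reach[iri])
            for parent in reach[iri]:
                new |= reach[parent]
            if new != reach[iri]:
                reach[iri] = new
                changed = True
    return reach


def random_alignment(
    rng: np.random.Generator, n_mappings: int, universe: int = 40
) -> Alignment:
    """A random equivalence alignment over a small IRI universe (so
    random pairs of alignments overlap)."""
    alignment = Alignment("A", "B")
    for _ in range(n_mappings):
        alignment.add(
            Mapping(
                source_iri=f"urn:a:{int(rng.integers(universe))}",
                target_iri=f"urn:b:{int(rng.integers(universe))}",
                confidence=float(rng.random()),
            )
        )
    return alignment


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(seed=7, classes_per_category=20)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)
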