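import random

import pytest

from mirmesh import (
    MeshOntology,
    MeshTerm,
    study_corpus,
    study_ontology,
    study_plan,
)


@pytest.fixture(scope="session")
def onto():
    return study_ontology()


@pytest.fixture(scope="session")
def corpus():
    return study_corpus()


@pytest.fixture(scope="session")
def plan():
    return study_plan()


def make_random_dag(rng: random.Random, max_nodes: int = 12) -> MeshOntology:
    """A random small DAG: node i may take parents among nodes < i, so the
    structure is acyclic by construction (including multi-parent nodes)."""
    n = rng.randint(1, max_nodes)
    terms = {}
    for i in range(n):
        tid = f"n{i}"
        candidates = [f"n{j}" for j in range(i)]
        parents = tuple(
            sorted(rng.sample(candidates, rng.randint(0, min(3, len(candidates)))))
        )
        terms[tid] = MeshTerm(
            term_id=tid, preferred_label=f"Node {i}", parent_ids=parents
        )
    return MeshOntology(terms=terms)
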