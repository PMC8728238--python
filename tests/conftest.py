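"""Shared helpers: toy ontology builders and an independent reachability
oracle (boolean Floyd-Warshall transitive closure) used to check ancestor
queries and annotation closure against a second algorithm."""

import numpy as np
import pytest

from goxfer.ontology import GoTerm, OntologyGraph

_NS = {
    "F": "molecular_function",
    "P": "biological_process",
    "C": "cellular_component",
}


def graph_from(edges, aspects=None, extra_terms=(), obsolete=(),
               closure_relations=("is_a", "part_of")):
    """Build an OntologyGraph from (child, relation, parent) triples.

    ``aspects`` maps term id -> aspect letter (default P).
    """
    ids = {e[0] for e in edges} | {e[2] for e in edges} | set(extra_terms) | set(obsolete)
    aspects = aspects or {}
    terms = {
        i: GoTerm(
            id=i,
            name=f"name of {i}",
            aspect=_NS[aspects.get(i, "P")],
            obsolete=i in set(obsolete),
        )
        for i in ids
    }
    return OntologyGraph(terms, edges, closure_relations=closure_relations)


def random_dag_edges(rng, n, density=0.15, relations=("is_a", "part_of")):
    """Random DAG: term ranks with forward-only edges (acyclic by
    construction).  Returns (ids, edges)."""
    ids = [f"GO:{i:07d}" for i in range(1, n + 1)]
    edges = []
    for i in range(1, n):
        edges.append((ids[i], "is_a", ids[int(rng.integers(0, i))]))
    for i in range(n):
        for j in range(i):
            if rng.random() < density:
                rel = relations[int(rng.integers(0, len(relations)))]
                edges.append((ids[i], rel, ids[j]))
    return ids, sorted(set(edges))


def transitive_reach(ids, edges, relations):
    """Independent oracle: boolean Floyd-Warshall transitive closure over
    edges whose relation is in ``relations``.  Returns id -> set of
    reachable ids (excluding the id itself unless on a cycle)."""
    idx = {t: i for i, t in enumerate(ids)}
    n = len(ids)
    reach = np.zeros((n, n), dtype=bool)
    for child, rel, parent in edges:
        if rel in relations:
            reach[idx[child], idx[parent]] = True
    for k in range(n):
        reach |= np.outer(reach[:, k], reach[k, :])
    return {
        t: {ids[j] for j in range(n) if reach[idx[t], j]} for t in ids
    }


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default synthetic bundle plus its pipeline result, shared across
    tests that only read from it."""
    from goxfer import FixtureSpec, make_bundle, run_pipeline

    d = tmp_path_factory.mktemp("bundle")
    b, truth = make_bundle(FixtureSpec(seed=3), str(d))
    result = run_pipeline(b.config)
    return b, truth, result
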