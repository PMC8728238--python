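"""Gene Ontology DAG: OBO parsing, ancestor queries, annotation closure and
cross-aspect inference.

The ontology is a directed acyclic graph with typed edges (``is_a``,
``part_of``, ...).  Annotation closure implements the true-path rule: an
annotation to a term implies annotation to all its parents along the
configured closure relations (default ``is_a`` and ``part_of``).
Cross-aspect inference follows inter-ontology link edges — relationship
edges that connect terms in different GO namespaces, such as a molecular
function that is ``part_of`` a biological process — and adds inferred
annotations in the target aspect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import IO, Iterable, Optional, Union

import networkx as nx

from .formats_io import AnnotationRecord, ParseStats, dedup_records

#: Relations used for "parent" semantics in the true-path closure.
DEFAULT_CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})

#: Inter-ontology inference channels: (relation, source aspect, target
#: aspect).  A gene annotated to a molecular-function term that is
#: ``part_of`` a biological-process term gains an inferred BP annotation;
#: a BP term that ``occurs_in`` a cellular component yields an inferred CC
#: annotation.
DEFAULT_LINK_CHANNELS = (
    ("part_of", "F", "P"),
    ("occurs_in", "P", "C"),
)

NAMESPACE_TO_ASPECT = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}


class OboParseError(ValueError):
    """Malformed OBO input; the message names the offending line."""


class OntologyValidationError(ValueError):
    """The parsed structure violates an ontology invariant (cycles,
    dangling edges, ambiguous alt_ids)."""


class UnknownTermError(KeyError):
    """A GO identifier that resolves to no term, not even via alt_id."""


@dataclass(frozen=True)
class GoTerm:
    id: str
    name: str
    aspect: str  # namespace: molecular_function / biological_process / cellular_component
    obsolete: bool = False
    alt_ids: frozenset = frozenset()


class OntologyGraph:
    """GO terms plus typed directed edges (child, relation, parent).

    Edges never touch obsolete terms.  The subgraph restricted to
    ``closure_relations`` must be acyclic; a cycle raises
    :class:`OntologyValidationError` listing one offending cycle.
    """

    def __init__(
        self,
        terms: dict,
        edges: Iterable[tuple],
        closure_relations: Iterable[str] = DEFAULT_CLOSURE_RELATIONS,
    ):
        self.terms = dict(terms)
        self.edges = set(edges)
        self.closure_relations = frozenset(closure_relations)
        self.alt_hits = 0  # alt_id lookups resolved silently to primary ids

        self._alt: dict = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                if alt in self._alt and self._alt[alt] != term.id:
                    raise OntologyValidationError(
                        f"alt_id {alt} maps to both {self._alt[alt]} and {term.id}"
                    )
                self._alt[alt] = term.id

        self._graph = nx.MultiDiGraph()
        self._graph.add_nodes_from(self.terms)
        for child, relation, parent in self.edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise OntologyValidationError(
                        f"edge ({child}, {relation}, {parent}) references "
                        f"unknown term {endpoint}"
                    )
                if self.terms[endpoint].obsolete:
                    raise OntologyValidationError(
                        f"edge ({child}, {relation}, {parent}) touches "
                        f"obsolete term {endpoint}"
                    )
            self._graph.add_edge(child, parent, key=relation)

        closure_sub = nx.DiGraph(
            (c, p)
            for c, relation, p in self.edges
            if relation in self.closure_relations
        )
        if not nx.is_directed_acyclic_graph(closure_sub):
            cycle = nx.find_cycle(closure_sub)
            path = " -> ".join([edge[0] for edge in cycle] + [cycle[0][0]])
            raise OntologyValidationError(f"cyclic structure: {path}")

    # -- lookups ------------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def resolve(self, term_id: str) -> str:
        """Return the primary id for ``term_id``, following alt_ids."""
        if term_id in self.terms:
            return term_id
        if term_id in self._alt:
            self.alt_hits += 1
            return self._alt[term_id]
        raise UnknownTermError(term_id)

    def aspect_of(self, term_id: str) -> str:
        """Single-letter aspect (F/P/C) of a term."""
        return NAMESPACE_TO_ASPECT[self.terms[self.resolve(term_id)].aspect]

    def relation_labels(self) -> frozenset:
        return frozenset(rel for _, rel, _ in self.edges)

    # -- traversal ----------------------------------------------------------

    def ancestors(
        self, term_id: str, relations: Optional[Iterable[str]] = None
    ) -> set:
        """All terms reachable from ``term_id`` along edges whose relation
        is in ``relations`` (default: the closure relations), excluding the
        term itself."""
        start = self.resolve(term_id)
        wanted = (
            self.closure_relations if relations is None else frozenset(relations)
        )
        seen: set = set()
        stack = [start]
        while stack:
            node = stack.pop()
            for _, parent, relation in self._graph.out_edges(node, keys=True):
                if relation in wanted and parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    def direct_parents(self, term_id: str, relation: str) -> set:
        """Terms one ``relation`` edge above ``term_id``."""
        start = self.resolve(term_id)
        return {
            parent
            for _, parent, rel in self._graph.out_edges(start, keys=True)
            if rel == relation
        }

    # -- export -------------------------------------------------------------

    def write_edge_tsv(self, stream: IO[str]) -> None:
        """Debug export: one ``child<TAB>relation<TAB>parent`` line per edge."""
        for child, relation, parent in sorted(self.edges):
            stream.write(f"{child}\t{relation}\t{parent}\n")


# ---------------------------------------------------------------------------
# OBO parsing


def _as_lines(stream: Union[str, IO[str]]):
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return stream


def parse_obo(
    stream: Union[str, IO[str]],
    closure_relations: Iterable[str] = DEFAULT_CLOSURE_RELATIONS,
) -> OntologyGraph:
    """Parse the go.obo flat-file dialect into an :class:`OntologyGraph`.

    Supported tags: ``id``, ``name``, ``namespace``, ``alt_id``, ``is_a``,
    ``relationship``, ``is_obsolete``.  Obsolete terms are recorded but
    excluded from all edges.  A ``[Term]`` stanza without an ``id`` raises
    :class:`OboParseError` naming its starting line.
    """
    terms: dict = {}
    raw_edges: list = []
    default_namespace: Optional[str] = None

    stanza: Optional[dict] = None
    stanza_line = 0

    def flush():
        if stanza is None:
            return
        term_id = stanza.get("id")
        if not term_id:
            raise OboParseError(
                f"[Term] stanza starting at line {stanza_line} has no id tag"
            )
        namespace = stanza.get("namespace") or default_namespace
        if namespace not in NAMESPACE_TO_ASPECT:
            raise OboParseError(
                f"term {term_id} (stanza at line {stanza_line}) has missing "
                f"or unrecognized namespace {namespace!r}"
            )
        obsolete = stanza.get("obsolete", False)
        if term_id in terms:
            raise OboParseError(
                f"duplicate term id {term_id} (stanza at line {stanza_line})"
            )
        terms[term_id] = GoTerm(
            id=term_id,
            name=stanza.get("name", ""),
            aspect=namespace,
            obsolete=obsolete,
            alt_ids=frozenset(stanza.get("alt_ids", ())),
        )
        if not obsolete:
            for relation, parent in stanza.get("edges", ()):
                raw_edges.append((term_id, relation, parent))

    for lineno, raw in enumerate(_as_lines(stream), 1):
        line = raw.strip()
        if line.startswith("["):
            flush()
            stanza = {"alt_ids": [], "edges": []} if line == "[Term]" else None
            stanza_line = lineno
            continue
        if not line or line.startswith("!"):
            continue
        if ":" not in line:
            continue
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = value.strip()
        if stanza is None:
            if tag == "default-namespace":
                default_namespace = value
            continue
        if tag in ("is_a", "alt_id", "relationship"):
            value = value.split("!")[0].strip()
        if tag == "id":
            stanza["id"] = value
        elif tag == "name":
            stanza["name"] = value
        elif tag == "namespace":
            stanza["namespace"] = value
        elif tag == "alt_id":
            stanza["alt_ids"].append(value)
        elif tag == "is_a":
            stanza["edges"].append(("is_a", value))
        elif tag == "is_obsolete":
            stanza["obsolete"] = value.lower() == "true"
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(
                    f"line {lineno}: malformed relationship value {value!r}"
                )
            stanza["edges"].append((parts[0], parts[1]))
    flush()

    # drop edges whose parent is obsolete (obsolete terms carry no edges)
    edges = [
        (c, r, p)
        for c, r, p in raw_edges
        if not (p in terms and terms[p].obsolete)
    ]
    return OntologyGraph(terms, edges, closure_relations=closure_relations)


# ---------------------------------------------------------------------------
# Annotation closure and cross-aspect inference


def close_annotations(
    graph: OntologyGraph,
    records: Iterable[AnnotationRecord],
    stats: Optional[ParseStats] = None,
) -> set:
    """True-path closure: add, for every record (g, t) and every ancestor
    ``a`` of ``t`` under the graph's closure relations, a record (g, a)
    carrying the child's evidence and provenance ``closure``.

    Input records survive unchanged (terms resolved to primary ids);
    records on obsolete terms are dropped and counted.  The result is
    deduplicated and idempotent: ``close(close(X)) == close(X)``.
    """
    out: list = []
    for rec in records:
        primary = graph.resolve(rec.term)
        if graph.terms[primary].obsolete:
            if stats is not None:
                stats.inc("obsolete_term_records")
            continue
        if primary != rec.term:
            rec = replace(rec, term=primary, aspect=graph.aspect_of(primary))
        out.append(rec)
        for ancestor in graph.ancestors(primary):
            out.append(
                replace(
                    rec,
                    term=ancestor,
                    aspect=graph.aspect_of(ancestor),
                    source="closure",
                    with_from="",
                )
            )
    return dedup_records(out)


def infer_cross_aspect(
    graph: OntologyGraph,
    records: Iterable[AnnotationRecord],
    link_channels: Iterable[tuple] = DEFAULT_LINK_CHANNELS,
) -> set:
    """Inter-ontology inference: return only the newly inferred records.

    For every channel (relation, source aspect, target aspect) and every
    positive record on a source-aspect term with a direct ``relation`` edge
    to a target-aspect term, emit an inferred record on the target term
    with evidence IEA and provenance ``inter-ontology``.  NOT-qualified
    records never seed inference.
    """
    channels = tuple(link_channels)
    inferred: list = []
    for rec in records:
        if rec.is_negative:
            continue
        primary = graph.resolve(rec.term)
        if graph.terms[primary].obsolete:
            continue
        aspect = graph.aspect_of(primary)
        for relation, source_aspect, target_aspect in channels:
            if aspect != source_aspect:
                continue
            for parent in graph.direct_parents(primary, relation):
                if graph.aspect_of(parent) != target_aspect:
                    continue
                inferred.append(
                    replace(
                        rec,
                        term=parent,
                        aspect=target_aspect,
                        evidence="IEA",
                        source="inter-ontology",
                        with_from=primary,
                    )
                )
    return dedup_records(inferred)
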