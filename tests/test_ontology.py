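"""Ontology parsing, ancestor queries, closure and cross-aspect inference."""

import io

import numpy as np
import pytest

from conftest import graph_from, random_dag_edges, transitive_reach
from goxfer.formats_io import AnnotationRecord, ParseStats
from goxfer.ontology import (
    OboParseError,
    OntologyValidationError,
    UnknownTermError,
    close_annotations,
    infer_cross_aspect,
    parse_obo,
)

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: A
namespace: molecular_function

[Term]
id: GO:0000002
name: B
namespace: molecular_function
is_a: GO:0000001 ! A

[Term]
id: GO:0000003
name: C
namespace: molecular_function
is_a: GO:0000002 ! B
alt_id: GO:0000099
"""


class TestParseObo:
    def test_chain(self):
        g = parse_obo(CHAIN_OBO)
        assert set(g.terms) == {"GO:0000001", "GO:0000002", "GO:0000003"}
        assert g.edges == {
            ("GO:0000002", "is_a", "GO:0000001"),
            ("GO:0000003", "is_a", "GO:0000002"),
        }

    def test_obsolete_term_present_but_edgeless(self):
        obo = CHAIN_OBO + (
            "\n[Term]\nid: GO:0000004\nname: D\nnamespace: molecular_function\n"
            "is_obsolete: true\nis_a: GO:0000001\n"
        )
        g = parse_obo(obo)
        assert g.terms["GO:0000004"].obsolete
        assert not any("GO:0000004" in (c, p) for c, _, p in g.edges)

    def test_relationship_becomes_typed_edge(self):
        obo = CHAIN_OBO + (
            "\n[Term]\nid: GO:0000005\nname: E\nnamespace: biological_process\n"
            "relationship: part_of GO:0000001 ! A\n"
        )
        g = parse_obo(obo)
        assert ("GO:0000005", "part_of", "GO:0000001") in g.edges

    def test_missing_id_names_line(self):
        obo = "[Term]\nname: anonymous\nnamespace: molecular_function\n"
        with pytest.raises(OboParseError, match="line 1"):
            parse_obo(obo)

    def test_cycle_reported(self):
        obo = (
            "[Term]\nid: GO:0000001\nname: A\nnamespace: molecular_function\n"
            "is_a: GO:0000002\n\n"
            "[Term]\nid: GO:0000002\nname: B\nnamespace: molecular_function\n"
            "is_a: GO:0000001\n"
        )
        with pytest.raises(OntologyValidationError, match="cyclic"):
            parse_obo(obo)

    def test_unknown_edge_endpoint_rejected(self):
        obo = (
            "[Term]\nid: GO:0000001\nname: A\nnamespace: molecular_function\n"
            "is_a: GO:0009999\n"
        )
        with pytest.raises(OntologyValidationError, match="GO:0009999"):
            parse_obo(obo)

    def test_typedef_stanzas_ignored(self):
        obo = CHAIN_OBO + "\n[Typedef]\nid: part_of\nname: part of\n"
        assert len(parse_obo(obo).terms) == 3


class TestAncestors:
    def test_root_has_no_ancestors(self):
        g = parse_obo(CHAIN_OBO)
        assert g.ancestors("GO:0000001") == set()

    def test_chain(self):
        g = parse_obo(CHAIN_OBO)
        assert g.ancestors("GO:0000003", {"is_a"}) == {
            "GO:0000002",
            "GO:0000001",
        }

    def test_alt_id_resolves_to_primary(self):
        g = parse_obo(CHAIN_OBO)
        assert g.resolve("GO:0000099") == "GO:0000003"
        assert g.ancestors("GO:0000099") == {"GO:0000002", "GO:0000001"}
        assert g.alt_hits >= 1

    def test_unknown_term_raises(self):
        g = parse_obo(CHAIN_OBO)
        with pytest.raises(UnknownTermError):
            g.ancestors("GO:7777777")

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_transitive_reachability_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 51))
        ids, edges = random_dag_edges(rng, n)
        g = graph_from(edges, extra_terms=ids)
        for relations in ({"is_a"}, {"is_a", "part_of"}):
            oracle = transitive_reach(ids, edges, relations)
            for t in ids:
                assert g.ancestors(t, relations) == oracle[t]


def _rec(gene, term, **kw):
    kw.setdefault("aspect", "P")
    return AnnotationRecord(subject_id=gene, term=term, **kw)


class TestClosure:
    def test_root_annotation_is_fixed_point(self):
        g = parse_obo(CHAIN_OBO)
        recs = {_rec("g1", "GO:0000001", aspect="F", source="uniprot")}
        assert close_annotations(g, recs) == recs

    def test_chain_produces_three_records(self):
        g = parse_obo(CHAIN_OBO)
        out = close_annotations(
            g, {_rec("g1", "GO:0000003", aspect="F", source="uniprot")}
        )
        assert {(r.subject_id, r.term) for r in out} == {
            ("g1", "GO:0000003"),
            ("g1", "GO:0000002"),
            ("g1", "GO:0000001"),
        }
        closure_recs = {r for r in out if r.source == "closure"}
        assert len(closure_recs) == 2
        assert all(r.evidence == "IEA" for r in closure_recs)

    def test_obsolete_record_dropped_and_counted(self):
        obo = CHAIN_OBO + (
            "\n[Term]\nid: GO:0000004\nname: D\nnamespace: molecular_function\n"
            "is_obsolete: true\n"
        )
        g = parse_obo(obo)
        stats = ParseStats()
        out = close_annotations(g, {_rec("g1", "GO:0000004")}, stats=stats)
        assert out == set()
        assert stats.get("obsolete_term_records") == 1

    @pytest.mark.parametrize("trial", range(10))
    def test_idempotent_and_monotone_on_random_inputs(self, trial):
        rng = np.random.default_rng(7 + trial)
        ids, edges = random_dag_edges(rng, int(rng.integers(5, 30)))
        g = graph_from(edges, extra_terms=ids)
        recs = {
            _rec(f"g{rng.integers(0, 4)}", ids[int(rng.integers(0, len(ids)))],
                 source="uniprot")
            for _ in range(8)
        }
        once = close_annotations(g, recs)
        assert close_annotations(g, once) == once
        assert recs <= once  # never removes an input record
        assert all(r.term in g.terms for r in once)

    def test_isa_closure_subset_of_isa_partof_closure(self):
        rng = np.random.default_rng(42)
        ids, edges = random_dag_edges(rng, 25)
        recs = {_rec("g1", ids[-1], source="uniprot")}
        g_isa = graph_from(edges, extra_terms=ids, closure_relations=("is_a",))
        g_both = graph_from(edges, extra_terms=ids)
        terms_isa = {r.term for r in close_annotations(g_isa, recs)}
        terms_both = {r.term for r in close_annotations(g_both, recs)}
        assert terms_isa <= terms_both


class TestCrossAspectInference:
    def _graph(self):
        # F2 --part_of--> P1; P2 --occurs_in--> C1
        return graph_from(
            [
                ("GO:0000002", "part_of", "GO:0000010"),
                ("GO:0000011", "occurs_in", "GO:0000020"),
                ("GO:0000011", "is_a", "GO:0000010"),
            ],
            aspects={
                "GO:0000002": "F",
                "GO:0000010": "P",
                "GO:0000011": "P",
                "GO:0000020": "C",
            },
        )

    def test_mf_part_of_bp_infers_bp_record(self):
        g = self._graph()
        out = infer_cross_aspect(
            g, {_rec("g1", "GO:0000002", aspect="F", source="uniprot")}
        )
        assert len(out) == 1
        (rec,) = out
        assert (rec.term, rec.aspect) == ("GO:0000010", "P")
        assert rec.source == "inter-ontology"
        assert rec.evidence == "IEA"

    def test_no_cross_edges_means_no_inference(self):
        g = self._graph()
        out = infer_cross_aspect(
            g, {_rec("g1", "GO:0000011", aspect="P", source="uniprot")},
            link_channels=[("part_of", "F", "P")],
        )
        assert out == set()

    def test_not_qualified_records_never_seed_inference(self):
        g = self._graph()
        out = infer_cross_aspect(
            g,
            {_rec("g1", "GO:0000002", aspect="F", qualifier="NOT")},
        )
        assert out == set()

    def test_inference_then_closure_adds_parents_of_inferred(self):
        g = self._graph()
        recs = {_rec("g1", "GO:0000011", aspect="P", source="uniprot")}
        inferred = infer_cross_aspect(g, recs)
        assert {r.term for r in inferred} == {"GO:0000020"}
        closed = close_annotations(g, recs | inferred)
        # ancestors of the seed record appear alongside the inferred CC term
        assert {"GO:0000010", "GO:0000020", "GO:0000011"} <= {
            r.term for r in closed
        }


def test_agrees_with_obonet_on_fixture():
    """Cross-check term inventory and is_a ancestry against obonet."""
    obonet = pytest.importorskip("obonet")
    import networkx as nx

    g = parse_obo(CHAIN_OBO)
    net = obonet.read_obo(io.StringIO(CHAIN_OBO))
    assert set(net.nodes) == set(g.terms)
    for term in g.terms:
        # obonet edges point child -> parent, so ancestors are descendants
        assert g.ancestors(term, {"is_a"}) == nx.descendants(net, term)


def test_edge_tsv_export():
    g = parse_obo(CHAIN_OBO)
    buf = io.StringIO()
    g.write_edge_tsv(buf)
    lines = buf.getvalue().splitlines()
    assert lines == [
        "GO:0000002\tis_a\tGO:0000001",
        "GO:0000003\tis_a\tGO:0000002",
    ]
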