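"""The three annotation sources: UniProt ingest with the multi-gene
exclusion rule, domain-derived GO, and homology transfer."""

import numpy as np
import pytest

from goxfer.formats_io import (
    AnnotationRecord,
    HitRow,
    IdMapping,
    InterproRow,
    ParseStats,
)
from goxfer.transfer import (
    DomainProfile,
    ReferenceSet,
    best_hits,
    build_profiles,
    extract_domain_go,
    ingest_uniprot,
    reciprocal_best_hits,
    transfer_homology,
)


def _prot_rec(protein, term, aspect="F", **kw):
    return AnnotationRecord(
        subject_id=protein, subject_kind="protein", term=term, aspect=aspect, **kw
    )


def _hit(q, s, bits, ev=1e-20):
    return HitRow(q, s, 90.0, 100, 5, 0, 1, 100, 1, 100, ev, bits)


class TestIngestUniprot:
    def test_single_gene_mapping_re_subjects(self):
        m = IdMapping({"P1": frozenset({"G1"})})
        recs = {_prot_rec("P1", "GO:0000001"), _prot_rec("P1", "GO:0000002")}
        out = ingest_uniprot(recs, m)
        assert {(r.subject_id, r.term) for r in out} == {
            ("G1", "GO:0000001"),
            ("G1", "GO:0000002"),
        }
        assert all(r.subject_kind == "gene" and r.source == "uniprot" for r in out)

    def test_multi_gene_protein_excluded(self):
        m = IdMapping({"P2": frozenset({"G1", "G2"})})
        stats = ParseStats()
        out = ingest_uniprot({_prot_rec("P2", "GO:0000001")}, m, stats=stats)
        assert out == set()
        assert stats.get("uniprot_multi_gene_proteins") == 1

    def test_unmapped_protein_counted(self):
        stats = ParseStats()
        out = ingest_uniprot({_prot_rec("P3", "GO:0000001")}, IdMapping({}),
                             stats=stats)
        assert out == set()
        assert stats.get("uniprot_unmapped_proteins") == 1

    def test_not_qualified_records_excluded(self):
        m = IdMapping({"P1": frozenset({"G1"})})
        out = ingest_uniprot(
            {_prot_rec("P1", "GO:0000001", qualifier="NOT")}, m
        )
        assert out == set()

    def test_evidence_preserved(self):
        m = IdMapping({"P1": frozenset({"G1"})})
        (rec,) = ingest_uniprot({_prot_rec("P1", "GO:0000001", evidence="EXP")}, m)
        assert rec.evidence == "EXP"


class TestExtractDomainGo:
    MAP = IdMapping({"Q1": frozenset({"G1"})})

    def test_one_row_two_terms(self):
        rows = {InterproRow("Q1", "Pfam", "PF00001",
                            go_terms=frozenset({"GO:0000001", "GO:0000002"}))}
        out = extract_domain_go(rows, self.MAP)
        assert {(r.subject_id, r.term) for r in out} == {
            ("G1", "GO:0000001"),
            ("G1", "GO:0000002"),
        }
        assert all(r.evidence == "IEA" and r.source == "interpro" for r in out)

    def test_shared_term_collapses_with_signatures_joined(self):
        rows = {
            InterproRow("Q1", "Pfam", "PF00001", go_terms=frozenset({"GO:0000001"})),
            InterproRow("Q1", "SMART", "SM00001", go_terms=frozenset({"GO:0000001"})),
        }
        (rec,) = extract_domain_go(rows, self.MAP)
        assert rec.with_from == "PF00001|SM00001"

    def test_empty_go_terms_yield_nothing(self):
        rows = {InterproRow("Q1", "Pfam", "PF00001")}
        assert extract_domain_go(rows, self.MAP) == set()

    def test_unmapped_protein_skipped_and_counted(self):
        rows = {InterproRow("QX", "Pfam", "PF00001",
                            go_terms=frozenset({"GO:0000001"}))}
        stats = ParseStats()
        assert extract_domain_go(rows, self.MAP, stats=stats) == set()
        assert stats.get("interpro_unmapped_proteins") == 1


class TestBuildProfiles:
    def test_signatures_collected(self):
        rows = {
            InterproRow("Q1", "Pfam", "PF00001"),
            InterproRow("Q1", "Pfam", "PF00002"),
            InterproRow("Q1", "Pfam", "PF00001"),  # repeat collapses
        }
        profiles = build_profiles(rows)
        assert profiles["Q1"].signatures == {"PF00001", "PF00002"}

    def test_excluded_analysis_ignored(self):
        rows = {
            InterproRow("Q1", "Coils", "Coil"),
            InterproRow("Q1", "Pfam", "PF00001"),
        }
        assert build_profiles(rows)["Q1"].signatures == {"PF00001"}

    def test_analysis_match_case_insensitive(self):
        rows = {InterproRow("Q1", "PANTHER", "PTHR00001")}
        assert build_profiles(rows, analyses={"Panther"})["Q1"].signatures == {
            "PTHR00001"
        }

    def test_listed_proteins_get_empty_profiles(self):
        profiles = build_profiles(set(), proteins=["Q9"])
        assert profiles["Q9"] == DomainProfile("Q9", frozenset())

    def test_interpro_granularity_integrates_signatures(self):
        rows = {
            InterproRow("Q1", "Pfam", "PF00001", interpro="IPR000001"),
            InterproRow("Q1", "SMART", "SM00001", interpro="IPR000001"),
            InterproRow("Q1", "Pfam", "PF00009"),  # no entry: ignored
        }
        profiles = build_profiles(rows, granularity="interpro")
        assert profiles["Q1"].signatures == {"IPR000001"}
        with pytest.raises(ValueError, match="granularity"):
            build_profiles(rows, granularity="entry")


class TestBestHits:
    def test_single_hit_wins(self):
        bh = best_hits({_hit("q", "r", 100)})
        assert bh.best == {"q": "r"}

    def test_higher_bit_score_wins(self):
        bh = best_hits({_hit("q", "a", 90), _hit("q", "b", 100)})
        assert bh.best == {"q": "b"}

    def test_tie_broken_by_evalue_then_subject(self):
        bh = best_hits({_hit("q", "B", 100, 1e-20), _hit("q", "A", 100, 1e-20)})
        assert bh.best == {"q": "A"}
        bh = best_hits({_hit("q", "A", 100, 1e-10), _hit("q", "B", 100, 1e-20)})
        assert bh.best == {"q": "B"}

    def test_evalue_threshold_applied_before_selection(self):
        stats = ParseStats()
        bh = best_hits(
            {_hit("q", "good", 50, 1e-10), _hit("q", "bad", 500, 1e-3)},
            max_evalue=1e-5,
            stats=stats,
        )
        assert bh.best == {"q": "good"}
        assert stats.get("hits_over_evalue") == 1

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(5)
        hits = {
            _hit(f"q{rng.integers(0, 5)}", f"r{rng.integers(0, 5)}",
                 float(rng.uniform(50, 400)))
            for _ in range(40)
        }
        assert best_hits(set(hits)).best == best_hits(set(hits)).best


class TestReciprocalBestHits:
    def test_mutual_pair(self):
        fwd = best_hits({_hit("q", "r", 300)})
        rev = best_hits({_hit("r", "q", 300)})
        assert reciprocal_best_hits(fwd, rev) == {("q", "r")}

    def test_non_mutual_is_empty(self):
        fwd = best_hits({_hit("q", "r", 300)})
        rev = best_hits({_hit("r", "q2", 300)})
        assert reciprocal_best_hits(fwd, rev) == set()

    def test_direction_mismatch_error(self):
        fwd = best_hits({_hit("q", "r", 300)}, query_species="a", ref_species="b")
        rev = best_hits({_hit("r", "q", 300)}, query_species="a", ref_species="b")
        with pytest.raises(ValueError, match="direction"):
            reciprocal_best_hits(fwd, rev)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        fwd_hits = {
            _hit(f"q{i}", f"r{rng.integers(0, 6)}", float(rng.uniform(50, 400)))
            for i in range(6)
        }
        rev_hits = {
            _hit(f"r{i}", f"q{rng.integers(0, 6)}", float(rng.uniform(50, 400)))
            for i in range(6)
        }
        fwd, rev = best_hits(fwd_hits), best_hits(rev_hits)
        assert reciprocal_best_hits(fwd, rev) == {
            (q, r) for r, q in reciprocal_best_hits(rev, fwd)
        }


def _ref(is_human=False, terms=("GO:0000001", "GO:0000002", "GO:0000003")):
    aspects = dict(zip(terms, ("F", "P", "C")))
    annotations = {_prot_rec("r1", t, aspects[t], source="reference")
                   for t in terms}
    return ReferenceSet(name="human" if is_human else "dmel",
                        annotations=annotations, is_human=is_human)


QMAP = IdMapping({"q1": frozenset({"QG1"}), "q2": frozenset({"QG1"})})


class TestTransferHomology:
    def test_rbh_transfers_all_aspects_from_non_human(self):
        fwd = best_hits({_hit("q1", "r1", 300)})
        rev = best_hits({_hit("r1", "q1", 300)})
        rbh = reciprocal_best_hits(fwd, rev)
        out = transfer_homology(rbh, fwd, {}, {}, _ref(), QMAP)
        assert {(r.term, r.aspect) for r in out} == {
            ("GO:0000001", "F"),
            ("GO:0000002", "P"),
            ("GO:0000003", "C"),
        }
        assert all(
            r.source == "homology:dmel" and r.with_from == "r1"
            and r.evidence == "IEA" for r in out
        )

    def test_human_reference_withholds_bp(self):
        fwd = best_hits({_hit("q1", "r1", 300)})
        rev = best_hits({_hit("r1", "q1", 300)})
        rbh = reciprocal_best_hits(fwd, rev)
        out = transfer_homology(rbh, fwd, {}, {}, _ref(is_human=True), QMAP)
        assert {(r.term, r.aspect) for r in out} == {
            ("GO:0000001", "F"),
            ("GO:0000003", "C"),
        }

    def test_best_hit_requires_identical_profiles(self):
        fwd = best_hits({_hit("q1", "r1", 200)})
        same = {"q1": DomainProfile("q1", frozenset({"PF1", "SM1"}))}
        ref_prof = {"r1": DomainProfile("r1", frozenset({"PF1", "SM1"}))}
        out = transfer_homology(set(), fwd, same, ref_prof, _ref(), QMAP)
        assert {r.term for r in out} == {"GO:0000001", "GO:0000002", "GO:0000003"}

        diff = {"q1": DomainProfile("q1", frozenset({"PF1"}))}
        out = transfer_homology(set(), fwd, diff, ref_prof, _ref(), QMAP)
        assert out == set()

    def test_no_term_invention(self):
        fwd = best_hits({_hit("q1", "r1", 300)})
        rev = best_hits({_hit("r1", "q1", 300)})
        ref = _ref()
        out = transfer_homology(
            reciprocal_best_hits(fwd, rev), fwd, {}, {}, ref, QMAP
        )
        ref_terms = {r.term for r in ref.annotations}
        assert {r.term for r in out} <= ref_terms

    def test_unmapped_query_counted(self):
        fwd = best_hits({_hit("qX", "r1", 300)})
        rev = best_hits({_hit("r1", "qX", 300)})
        stats = ParseStats()
        out = transfer_homology(
            reciprocal_best_hits(fwd, rev), fwd, {}, {}, _ref(),
            IdMapping({}), stats=stats,
        )
        assert out == set()
        assert stats.get("transfer_unmapped_query_proteins") == 1

    def test_isoforms_union_onto_gene(self):
        # two isoforms of QG1, each reciprocal with a different reference
        annotations = {
            _prot_rec("r1", "GO:0000001", "F", source="reference"),
            _prot_rec("r2", "GO:0000002", "P", source="reference"),
        }
        ref = ReferenceSet(name="dmel", annotations=annotations)
        fwd = best_hits({_hit("q1", "r1", 300), _hit("q2", "r2", 300)})
        rev = best_hits({_hit("r1", "q1", 300), _hit("r2", "q2", 300)})
        out = transfer_homology(
            reciprocal_best_hits(fwd, rev), fwd, {}, {}, ref, QMAP
        )
        assert {(r.subject_id, r.term) for r in out} == {
            ("QG1", "GO:0000001"),
            ("QG1", "GO:0000002"),
        }

    def test_not_qualified_reference_records_never_transfer(self):
        annotations = {
            _prot_rec("r1", "GO:0000001", "F", source="reference"),
            _prot_rec("r1", "GO:0000009", "F", source="reference",
                      qualifier="NOT"),
        }
        ref = ReferenceSet(name="dmel", annotations=annotations)
        fwd = best_hits({_hit("q1", "r1", 300)})
        rev = best_hits({_hit("r1", "q1", 300)})
        out = transfer_homology(
            reciprocal_best_hits(fwd, rev), fwd, {}, {}, ref, QMAP
        )
        assert {r.term for r in out} == {"GO:0000001"}

    def test_gene_level_reference_routed_through_mapping(self):
        annotations = {
            AnnotationRecord(subject_id="RG1", subject_kind="gene",
                             term="GO:0000001", aspect="F", source="reference")
        }
        ref = ReferenceSet(
            name="dmel",
            annotations=annotations,
            protein_to_gene=IdMapping({"r1": frozenset({"RG1"})}),
        )
        fwd = best_hits({_hit("q1", "r1", 300)})
        rev = best_hits({_hit("r1", "q1", 300)})
        out = transfer_homology(
            reciprocal_best_hits(fwd, rev), fwd, {}, {}, ref, QMAP
        )
        assert {(r.subject_id, r.term) for r in out} == {("QG1", "GO:0000001")}
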