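"""The three annotation sources feeding the merged GO set.

1. Curated annotations ingested from UniProt-GOA GAF files, with protein
   ids converted to gene ids; a protein mapping to more than one gene is
   excluded entirely (the multi-gene exclusion rule).
2. Domain-derived annotations: GO terms looked up by InterProScan for
   matching domain signatures.
3. Homology transfer from annotated reference proteomes: all GO terms of a
   reference protein are copied to a query protein when the pair is a
   reciprocal best hit, or when the reference is the query's
   (non-reciprocal) best hit and both proteins have identical domain
   content.  From a human reference only molecular-function and
   cellular-component terms are transferred, never biological-process
   terms, because process annotations transfer poorly across such large
   evolutionary distances.

All computed transfers carry evidence code IEA (inferred from electronic
annotation), the GO convention for unreviewed computational assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .formats_io import (
    AnnotationRecord,
    HitRow,
    IdMapping,
    InterproRow,
    ParseStats,
    dedup_records,
)

#: InterProScan member databases whose signatures define domain content.
DEFAULT_ANALYSES = frozenset({"Pfam", "SMART", "SUPERFAMILY", "PANTHER"})

#: E-value cutoff applied before best-hit selection; a conventional
#: protein-homology threshold.
DEFAULT_MAX_EVALUE = 1e-5


@dataclass(frozen=True)
class DomainProfile:
    """The set of domain-signature accessions observed on a protein,
    restricted to the configured analyses.  Two profiles are identical iff
    their signature sets are equal (copy number and order are ignored)."""

    protein: str
    signatures: frozenset = frozenset()


@dataclass
class BestHitMap:
    """Per-query best search hit in one direction of a species pair."""

    best: dict
    query_species: Optional[str] = None
    ref_species: Optional[str] = None

    def __getitem__(self, query: str) -> str:
        return self.best[query]

    def get(self, query: str):
        return self.best.get(query)

    def __len__(self) -> int:
        return len(self.best)


@dataclass
class ReferenceSet:
    """An annotated reference proteome used as a transfer source.

    ``annotations`` may be protein-level (subjects are the searched
    proteins) or gene-level, in which case ``protein_to_gene`` maps the
    searched reference proteins to the annotated genes.  ``is_human``
    activates the aspect restriction: biological-process terms are never
    transferred from the human reference.
    """

    name: str
    annotations: set
    protein_to_gene: Optional[IdMapping] = None
    is_human: bool = False

    def protein_annotations(self) -> dict:
        """Map reference protein -> set of positive annotation records."""
        by_subject: dict = {}
        for rec in self.annotations:
            if rec.is_negative:
                continue
            by_subject.setdefault(rec.subject_id, set()).add(rec)
        if all(
            rec.subject_kind == "protein"
            for recs in by_subject.values()
            for rec in recs
        ):
            return by_subject
        # gene-level annotations: route through the protein->gene table
        if self.protein_to_gene is None:
            raise ValueError(
                f"reference {self.name} has gene-level annotations but no "
                "protein_to_gene mapping"
            )
        by_protein: dict = {}
        for protein, genes in self.protein_to_gene.protein_to_gene.items():
            recs = set()
            for gene in genes:
                recs |= by_subject.get(gene, set())
            if recs:
                by_protein[protein] = recs
        return by_protein


# ---------------------------------------------------------------------------
# Source 1: UniProt-GOA ingest


def ingest_uniprot(
    records: Iterable[AnnotationRecord],
    mapping: IdMapping,
    stats: Optional[ParseStats] = None,
) -> set:
    """Convert protein-level curated annotations to gene level.

    A record is kept only when its protein maps to exactly one gene;
    proteins with no mapping or with several genes contribute nothing and
    are counted (``uniprot_unmapped_proteins`` /
    ``uniprot_multi_gene_proteins``).  Evidence codes are preserved;
    provenance becomes ``uniprot``.  NOT-qualified records are excluded.
    """
    out = set()
    multi: set = set()
    unmapped: set = set()
    for rec in records:
        if rec.is_negative:
            if stats is not None:
                stats.inc("uniprot_not_qualified_records")
            continue
        genes = mapping.get(rec.subject_id)
        if len(genes) == 1:
            (gene,) = genes
            out.add(
                replace(
                    rec,
                    subject_id=gene,
                    subject_kind="gene",
                    symbol="",
                    object_type="gene",
                    source="uniprot",
                )
            )
        elif len(genes) > 1:
            multi.add(rec.subject_id)
        else:
            unmapped.add(rec.subject_id)
    if stats is not None:
        stats.inc("uniprot_multi_gene_proteins", len(multi))
        stats.inc("uniprot_unmapped_proteins", len(unmapped))
    return dedup_records(out)


# ---------------------------------------------------------------------------
# Source 2: InterPro domain-derived GO


def extract_domain_go(
    rows: Iterable[InterproRow],
    mapping: IdMapping,
    graph=None,
    stats: Optional[ParseStats] = None,
    taxon: Optional[int] = None,
    assigned_by: str = "",
) -> set:
    """Gene-level records from the GO terms InterProScan looked up for
    matching domains.

    Every (protein, GO id) pair yields one record with evidence IEA,
    ``with_from`` set to the matching signature accession and provenance
    ``interpro``; duplicates collapse (signatures joined by ``|``).
    Proteins absent from the mapping are skipped and counted.
    """
    out: list = []
    skipped: set = set()
    for row in rows:
        if not row.go_terms:
            continue
        genes = mapping.get(row.protein)
        if not genes:
            skipped.add(row.protein)
            continue
        for term in row.go_terms:
            aspect = None
            if graph is not None and term in graph:
                aspect = graph.aspect_of(term)
            for gene in genes:
                out.append(
                    AnnotationRecord(
                        subject_id=gene,
                        subject_kind="gene",
                        term=term,
                        aspect=aspect,
                        evidence="IEA",
                        with_from=row.signature,
                        source="interpro",
                        taxon=taxon,
                        assigned_by=assigned_by,
                    )
                )
    if stats is not None:
        stats.inc("interpro_unmapped_proteins", len(skipped))
    return dedup_records(out)


def build_profiles(
    rows: Iterable[InterproRow],
    analyses: Iterable[str] = DEFAULT_ANALYSES,
    proteins: Optional[Iterable[str]] = None,
    granularity: str = "signature",
) -> dict:
    """Domain profile per protein: the signature accessions of rows whose
    analysis is in ``analyses`` (matched case-insensitively, so "Panther"
    and "PANTHER" agree).  Proteins listed in ``proteins`` but lacking
    qualifying rows get empty profiles.

    ``granularity="interpro"`` compares InterPro entry accessions instead
    of member-database signatures (coarser: integrates signatures that map
    to the same entry; rows without an entry are ignored).
    """
    if granularity not in ("signature", "interpro"):
        raise ValueError(
            f"granularity must be 'signature' or 'interpro', got {granularity!r}"
        )
    wanted = {a.upper() for a in analyses}
    sigs: dict = {}
    for row in rows:
        sigs.setdefault(row.protein, set())
        if row.analysis.upper() not in wanted:
            continue
        if granularity == "signature":
            sigs[row.protein].add(row.signature)
        elif row.interpro:
            sigs[row.protein].add(row.interpro)
    for protein in proteins or ():
        sigs.setdefault(protein, set())
    return {
        protein: DomainProfile(protein=protein, signatures=frozenset(s))
        for protein, s in sigs.items()
    }


# ---------------------------------------------------------------------------
# Source 3: homology transfer


def best_hits(
    hits: Iterable[HitRow],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    query_species: Optional[str] = None,
    ref_species: Optional[str] = None,
    stats: Optional[ParseStats] = None,
) -> BestHitMap:
    """Select each query's best hit after discarding hits with
    e-value > ``max_evalue``.

    Best = maximal bit score; ties broken by minimal e-value, then by
    lexicographically smallest subject id, so the result is deterministic.
    """
    kept: dict = {}
    n_over = 0
    for hit in hits:
        if hit.e_value > max_evalue:
            n_over += 1
            continue
        incumbent = kept.get(hit.query)
        if incumbent is None or (
            -hit.bit_score,
            hit.e_value,
            hit.subject,
        ) < (-incumbent.bit_score, incumbent.e_value, incumbent.subject):
            kept[hit.query] = hit
    if stats is not None:
        stats.inc("hits_over_evalue", n_over)
    return BestHitMap(
        best={q: h.subject for q, h in kept.items()},
        query_species=query_species,
        ref_species=ref_species,
    )


def reciprocal_best_hits(fwd: BestHitMap, rev: BestHitMap) -> set:
    """Pairs (q, r) with fwd.best[q] == r and rev.best[r] == q."""
    if (
        fwd.query_species is not None
        and rev.query_species is not None
        and (fwd.query_species, fwd.ref_species)
        != (rev.ref_species, rev.query_species)
    ):
        raise ValueError(
            f"direction mismatch: forward is {fwd.query_species}->"
            f"{fwd.ref_species}, reverse is {rev.query_species}->"
            f"{rev.ref_species}"
        )
    return {
        (q, r) for q, r in fwd.best.items() if rev.best.get(r) == q
    }


def transfer_homology(
    rbh: set,
    fwd: BestHitMap,
    profiles_query: Mapping[str, DomainProfile],
    profiles_ref: Mapping[str, DomainProfile],
    ref: ReferenceSet,
    mapping_query: IdMapping,
    stats: Optional[ParseStats] = None,
    taxon: Optional[int] = None,
    assigned_by: str = "",
) -> set:
    """Transfer GO terms from reference proteins to query genes.

    For each query protein q: if (q, r) is a reciprocal best hit, all of
    r's terms transfer; otherwise, if r is q's best hit and the two
    proteins have identical domain content (equal signature sets), all of
    r's terms transfer; otherwise nothing.  When the reference is human,
    biological-process (aspect P) records are withheld.

    Transferred records: evidence IEA, ``with_from`` = the reference
    protein, provenance ``homology:<ref name>``, re-subjected to query
    genes via ``mapping_query`` (a multi-isoform gene receives the union
    over its proteins).
    """
    ref_ann = ref.protein_annotations()
    rbh_by_query = dict(sorted(rbh))
    out: list = []
    unmapped: set = set()

    candidates: dict = {}
    for q, r in rbh_by_query.items():
        candidates[q] = r
    for q, r in fwd.best.items():
        if q in candidates:
            continue
        pq = profiles_query.get(q)
        pr = profiles_ref.get(r)
        if pq is not None and pr is not None and pq.signatures == pr.signatures:
            candidates[q] = r

    for q in sorted(candidates):
        r = candidates[q]
        genes = mapping_query.get(q)
        source_records = ref_ann.get(r, set())
        if not source_records:
            continue
        if not genes:
            unmapped.add(q)
            continue
        for rec in source_records:
            if ref.is_human and rec.aspect == "P":
                if stats is not None:
                    stats.inc("human_bp_records_withheld")
                continue
            for gene in sorted(genes):
                out.append(
                    AnnotationRecord(
                        subject_id=gene,
                        subject_kind="gene",
                        term=rec.term,
                        aspect=rec.aspect,
                        evidence="IEA",
                        with_from=r,
                        source=f"homology:{ref.name}",
                        taxon=taxon,
                        assigned_by=assigned_by,
                    )
                )
    if stats is not None:
        stats.inc("transfer_unmapped_query_proteins", len(unmapped))
    return dedup_records(out)
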