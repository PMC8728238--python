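"""Pipeline orchestration: merge the three annotation sources, apply
inter-ontology inference and ancestor closure, and emit GAF, GeneMerge and
summary outputs.

Stage order is fixed: sources -> merge -> inter-ontology inference ->
ancestor closure, so inferred annotations also receive their ancestors.
Every discard class (multi-gene proteins, unmapped proteins, obsolete
terms, over-threshold hits) has a named counter reported in the summary.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional

import yaml

from . import ontology as onto
from . import transfer as xfer
from .formats_io import (
    AnnotationRecord,
    ParseStats,
    dedup_records,
    read_gaf,
    read_hits,
    read_idmapping,
    read_interproscan,
    write_gaf,
    write_genemerge,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class ReferenceSpec:
    """Input paths for one annotated reference species."""

    name: str
    gaf: str
    protein_to_gene: Optional[str] = None
    interproscan: Optional[str] = None
    hits_fwd: Optional[str] = None  # query species -> reference
    hits_rev: Optional[str] = None  # reference -> query species
    is_human: bool = False


@dataclass
class PipelineConfig:
    species: str
    taxon: int
    ontology: str
    out_dir: str = "out"
    uniprot_gaf: Optional[str] = None
    idmapping: Optional[str] = None
    idmapping_protein_col: int = 1
    idmapping_gene_col: int = 3
    interproscan: Optional[str] = None
    protein_to_gene: Optional[str] = None
    references: List[ReferenceSpec] = field(default_factory=list)
    max_evalue: float = xfer.DEFAULT_MAX_EVALUE
    analyses: tuple = tuple(sorted(xfer.DEFAULT_ANALYSES))
    assigned_by: str = "goxfer"
    closure_relations: tuple = tuple(sorted(onto.DEFAULT_CLOSURE_RELATIONS))
    gene_prefix: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if sum(1 for r in self.references if r.is_human) > 1:
            raise ValueError("at most one reference may be flagged is_human")
        for ref in self.references:
            if (ref.hits_fwd is None) != (ref.hits_rev is None):
                raise ValueError(
                    f"reference {ref.name}: both search directions are "
                    "required (hits_fwd and hits_rev)"
                )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        refs = [ReferenceSpec(**r) for r in raw.pop("references", [])]
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        if "closure_relations" in raw:
            raw["closure_relations"] = tuple(raw["closure_relations"])
        return cls(references=refs, **raw)

    def to_yaml(self, path: str) -> None:
        data = {
            k: v
            for k, v in self.__dict__.items()
            if k != "references" and v is not None
        }
        data["analyses"] = list(self.analyses)
        data["closure_relations"] = list(self.closure_relations)
        data["references"] = [dict(r.__dict__) for r in self.references]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class AnnotationSummary:
    """Distinct-gene and record counts for one species' annotation set."""

    species: str
    total_genes: int
    total_records: int
    genes_per_source: dict
    records_per_aspect: dict
    discards: dict

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "total_annotated_genes": self.total_genes,
            "total_records": self.total_records,
            "annotated_genes_per_source": self.genes_per_source,
            "records_per_aspect": self.records_per_aspect,
            "discards": self.discards,
        }


@dataclass
class PipelineResult:
    records: set
    summary: AnnotationSummary
    rbh: dict  # reference name -> set of (query protein, reference protein)
    graph: onto.OntologyGraph
    gaf_path: Optional[str] = None
    genemerge_path: Optional[str] = None
    summary_path: Optional[str] = None


def merge_sources(
    sets: Iterable[Iterable[AnnotationRecord]],
    gene_prefix: Optional[str] = None,
) -> set:
    """Union of gene-level record sets, deduplicated on
    (subject, qualifier, term, evidence, source); records differing only in
    ``with_from`` collapse with values joined by ``|``.  NOT-qualified
    records never enter the merged positive set.

    ``gene_prefix``, when configured, guards against mixing species: a
    subject id without the prefix raises :class:`PipelineError`.
    """
    pooled: list = []
    for records in sets:
        for rec in records:
            if rec.is_negative:
                continue
            if rec.subject_kind != "gene":
                raise PipelineError(
                    f"merge_sources requires gene-level records; got "
                    f"{rec.subject_kind} subject {rec.subject_id}"
                )
            if gene_prefix and not rec.subject_id.startswith(gene_prefix):
                raise PipelineError(
                    f"subject {rec.subject_id} does not match the configured "
                    f"gene namespace prefix {gene_prefix!r}"
                )
            pooled.append(rec)
    return dedup_records(pooled)


def summarize(
    records: Iterable[AnnotationRecord],
    per_source: dict,
    species: str = "",
    discards: Optional[dict] = None,
) -> AnnotationSummary:
    """Distinct-gene counts overall and per source, plus per-aspect record
    counts.  ``per_source`` maps a source label to that source's gene-level
    record set (pre-merge)."""
    records = set(records)
    genes_per_source = {
        label: len({r.subject_id for r in recs})
        for label, recs in sorted(per_source.items())
    }
    per_aspect: dict = {}
    for rec in records:
        key = rec.aspect or "unknown"
        per_aspect[key] = per_aspect.get(key, 0) + 1
    return AnnotationSummary(
        species=species,
        total_genes=len({r.subject_id for r in records}),
        total_records=len(records),
        genes_per_source=genes_per_source,
        records_per_aspect=dict(sorted(per_aspect.items())),
        discards=dict(sorted((discards or {}).items())),
    )


def aggregate_summaries(summaries: Iterable[AnnotationSummary]) -> dict:
    """Cross-species aggregate: total and mean annotated genes per species."""
    summaries = list(summaries)
    totals = [s.total_genes for s in summaries]
    return {
        "n_species": len(summaries),
        "total_annotated_genes": sum(totals),
        "mean_annotated_genes_per_species": (
            sum(totals) / len(totals) if totals else 0.0
        ),
    }


def _read(path: str, reader, *args, **kwargs):
    with open(path) as fh:
        return reader(fh, *args, **kwargs)


def run_pipeline(
    config: PipelineConfig, out_dir: Optional[str] = None
) -> PipelineResult:
    """Execute the full annotation pipeline and write ``<species>.gaf``,
    ``<species>.genemerge.txt`` and ``<species>.summary.json``.

    Any stage error aborts with the stage name; partial outputs are
    removed.
    """
    out_dir = out_dir or config.out_dir
    stats = ParseStats()
    stage = "configuration"
    outputs: list = []
    try:
        stage = "ontology"
        graph = _read(
            config.ontology,
            onto.parse_obo,
            closure_relations=frozenset(config.closure_relations),
        )

        stage = "query protein-to-gene mapping"
        query_p2g = None
        if config.protein_to_gene:
            query_p2g = _read(
                config.protein_to_gene, read_idmapping, protein_col=1, gene_col=2
            )

        stage = "uniprot ingest"
        sources: dict = {}
        if config.uniprot_gaf and config.idmapping:
            uniprot_records = _read(config.uniprot_gaf, read_gaf, stats=stats)
            idmap = _read(
                config.idmapping,
                read_idmapping,
                protein_col=config.idmapping_protein_col,
                gene_col=config.idmapping_gene_col,
                stats=stats,
            )
            sources["uniprot"] = xfer.ingest_uniprot(
                uniprot_records, idmap, stats=stats
            )
        else:
            sources["uniprot"] = set()

        stage = "interproscan domain-to-GO extraction"
        query_profiles: dict = {}
        if config.interproscan and query_p2g is not None:
            ipr_rows = _read(config.interproscan, read_interproscan, stats=stats)
            sources["interpro"] = xfer.extract_domain_go(
                ipr_rows,
                query_p2g,
                graph=graph,
                stats=stats,
                taxon=config.taxon,
                assigned_by=config.assigned_by,
            )
            query_profiles = xfer.build_profiles(
                ipr_rows,
                analyses=config.analyses,
                proteins=query_p2g.protein_to_gene,
            )
        else:
            sources["interpro"] = set()

        rbh_by_ref: dict = {}
        for ref_spec in config.references:
            stage = f"homology transfer from {ref_spec.name}"
            ref_p2g = None
            if ref_spec.protein_to_gene:
                ref_p2g = _read(
                    ref_spec.protein_to_gene,
                    read_idmapping,
                    protein_col=1,
                    gene_col=2,
                )
            ref = xfer.ReferenceSet(
                name=ref_spec.name,
                annotations=_read(
                    ref_spec.gaf, read_gaf, source="reference", stats=stats
                ),
                protein_to_gene=ref_p2g,
                is_human=ref_spec.is_human,
            )
            ref_profiles: dict = {}
            if ref_spec.interproscan:
                ref_profiles = xfer.build_profiles(
                    _read(ref_spec.interproscan, read_interproscan, stats=stats),
                    analyses=config.analyses,
                )
            fwd = xfer.best_hits(
                _read(ref_spec.hits_fwd, read_hits, stats=stats),
                max_evalue=config.max_evalue,
                query_species=config.species,
                ref_species=ref_spec.name,
                stats=stats,
            )
            rev = xfer.best_hits(
                _read(ref_spec.hits_rev, read_hits, stats=stats),
                max_evalue=config.max_evalue,
                query_species=ref_spec.name,
                ref_species=config.species,
                stats=stats,
            )
            rbh = xfer.reciprocal_best_hits(fwd, rev)
            rbh_by_ref[ref_spec.name] = rbh
            if query_p2g is None:
                raise PipelineError(
                    "homology transfer requires a query protein_to_gene table"
                )
            sources[f"homology:{ref_spec.name}"] = xfer.transfer_homology(
                rbh,
                fwd,
                query_profiles,
                ref_profiles,
                ref,
                query_p2g,
                stats=stats,
                taxon=config.taxon,
                assigned_by=config.assigned_by,
            )

        stage = "source merge"
        merged = merge_sources(sources.values(), gene_prefix=config.gene_prefix)

        stage = "inter-ontology inference"
        inferred = onto.infer_cross_aspect(graph, merged)

        stage = "ancestor closure"
        closed = onto.close_annotations(graph, merged | inferred, stats=stats)

        stage = "finalize"
        final = {
            replace(
                rec,
                taxon=config.taxon,
                assigned_by=rec.assigned_by or config.assigned_by,
            )
            for rec in closed
            if not rec.is_negative
        }
        if graph.alt_hits:
            stats.inc("alt_id_resolutions", graph.alt_hits)

        summary = summarize(
            final,
            per_source=sources,
            species=config.species,
            discards=stats.as_dict(),
        )

        stage = "output"
        os.makedirs(out_dir, exist_ok=True)
        gaf_path = os.path.join(out_dir, f"{config.species}.gaf")
        gm_path = os.path.join(out_dir, f"{config.species}.genemerge.txt")
        sum_path = os.path.join(out_dir, f"{config.species}.summary.json")
        outputs = [gaf_path, gm_path, sum_path]
        with open(gaf_path, "w") as fh:
            write_gaf(final, fh)
        with open(gm_path, "w") as fh:
            write_genemerge(final, fh)
        with open(sum_path, "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except PipelineError:
        _cleanup(outputs)
        raise
    except Exception as exc:
        _cleanup(outputs)
        raise PipelineError(f"stage '{stage}': {exc}") from exc

    return PipelineResult(
        records=final,
        summary=summary,
        rbh=rbh_by_ref,
        graph=graph,
        gaf_path=gaf_path,
        genemerge_path=gm_path,
        summary_path=sum_path,
    )


def _cleanup(paths: Iterable[str]) -> None:
    for path in paths:
        try:
            os.remove(path)
        except OSError:
            pass
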