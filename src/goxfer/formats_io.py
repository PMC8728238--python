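"""Readers and writers for the tabular formats the annotation pipeline touches.

Supported formats:

* GAF 2.1 (17-column Gene Association File) — the GO Consortium's
  annotation exchange format.
* UniProt ``idmapping_selected.tab`` — protein accession to gene id tables.
* InterProScan TSV output (with the GO-term column produced by
  ``-goterms``).
* 12-column tabular pairwise search results (BLAST ``-outfmt 6`` /
  FASTA ``-m 8`` style).
* GeneMerge association files (gene, TAB, semicolon-joined GO ids).

All writers use fixed sort orders and contain no timestamps in record
lines, so repeated runs on identical inputs are byte-identical and outputs
are diffable in tests.
"""

from __future__ import annotations

import io
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Optional, Union

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: Valid GAF aspect letters: molecular function, biological process,
#: cellular component.
ASPECTS = ("F", "P", "C")

#: Fixed date written into GAF column 14 so record lines carry no
#: run-dependent timestamps (determinism contract).
DEFAULT_GAF_DATE = "20200811"

GAF_VERSION_HEADER = "!gaf-version: 2.1"
_GAF_NCOLS = 17


class FormatError(ValueError):
    """A malformed input line; the message names the offending line."""


@dataclass
class ParseStats:
    """Named counters for warnings and discards accumulated while parsing
    and transforming annotation data.  Shared across pipeline stages so the
    final summary can report every discard class."""

    counts: Counter = field(default_factory=Counter)

    def inc(self, key: str, n: int = 1) -> None:
        self.counts[key] += n

    def get(self, key: str) -> int:
        return self.counts.get(key, 0)

    def as_dict(self) -> dict:
        return dict(sorted(self.counts.items()))


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-or-protein x GO-term assertion.

    ``source`` is the pipeline provenance tag: ``uniprot``, ``interpro``,
    ``homology:<ref>``, ``inter-ontology`` or ``closure``.  The remaining
    fields mirror GAF 2.1 columns so that a record read from a GAF file can
    be written back byte-identically.
    """

    subject_id: str
    term: str
    aspect: Optional[str] = None
    subject_kind: str = "gene"
    evidence: str = "IEA"
    qualifier: str = ""
    with_from: str = ""
    source: str = ""
    taxon: Optional[int] = None
    assigned_by: str = ""
    db: str = "goxfer"
    symbol: str = ""
    db_reference: str = "GO_REF:0000002"
    object_name: str = ""
    synonym: str = ""
    object_type: str = ""
    date: str = DEFAULT_GAF_DATE
    extension: str = ""
    gene_product_form: str = ""

    @property
    def is_negative(self) -> bool:
        """True for NOT-qualified records, which are never merged into
        positive annotation sets or transferred by homology."""
        return "NOT" in self.qualifier.split("|")


def dedup_key(record: AnnotationRecord) -> tuple:
    """Deduplication key: subject, kind, qualifier, term, evidence, source.

    Records differing only in ``with_from`` share a key and are collapsed
    with their with/from values joined by ``|``; records from distinct
    sources are kept apart so provenance stays auditable.
    """
    return (
        record.subject_id,
        record.subject_kind,
        record.qualifier,
        record.term,
        record.evidence,
        record.source,
    )


def _sort_key(record: AnnotationRecord) -> tuple:
    return (
        record.subject_id,
        record.term,
        record.evidence,
        record.source,
        record.qualifier,
        record.with_from,
        str(record.taxon),
        record.assigned_by,
    )


def dedup_records(records: Iterable[AnnotationRecord]) -> set:
    """Collapse records sharing :func:`dedup_key`.

    The representative record is the lexicographically first of each group;
    ``with_from`` becomes the ``|``-joined sorted union of the group's
    non-empty with/from entries.
    """
    groups: dict = {}
    for rec in sorted(records, key=_sort_key):
        groups.setdefault(dedup_key(rec), []).append(rec)
    out = set()
    for recs in groups.values():
        parts = sorted({p for r in recs for p in r.with_from.split("|") if p})
        out.add(replace(recs[0], with_from="|".join(parts)))
    return out


@dataclass(frozen=True)
class IdMapping:
    """Protein identifier -> set of gene identifiers."""

    protein_to_gene: Mapping[str, frozenset]

    def get(self, protein: str) -> frozenset:
        return self.protein_to_gene.get(protein, frozenset())

    def __contains__(self, protein: str) -> bool:
        return protein in self.protein_to_gene

    def __getitem__(self, protein: str) -> frozenset:
        return self.protein_to_gene[protein]

    def __len__(self) -> int:
        return len(self.protein_to_gene)

    def inverted(self) -> dict:
        """Gene identifier -> set of protein identifiers."""
        inv: dict = {}
        for prot, genes in self.protein_to_gene.items():
            for g in genes:
                inv.setdefault(g, set()).add(prot)
        return inv


@dataclass(frozen=True)
class HitRow:
    """One row of 12-column tabular pairwise-search output."""

    query: str
    subject: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float


@dataclass(frozen=True)
class InterproRow:
    """One InterProScan TSV line: a domain signature match on a protein,
    optionally carrying GO terms looked up for the matching domain."""

    protein: str
    analysis: str
    signature: str
    interpro: Optional[str] = None
    go_terms: frozenset = frozenset()


Stream = Union[str, IO[str]]


def _as_lines(stream: Stream):
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return stream


# ---------------------------------------------------------------------------
# GAF 2.1


def _parse_taxon(value: str, lineno: int, stats: Optional[ParseStats]):
    value = value.strip()
    if not value:
        return None
    first = value.split("|")[0]
    if first.lower().startswith("taxon:"):
        first = first[len("taxon:"):]
    try:
        return int(first)
    except ValueError:
        if stats is not None:
            stats.inc("gaf_unparseable_taxon")
        return None


def read_gaf(
    stream: Stream,
    source: str = "uniprot",
    stats: Optional[ParseStats] = None,
) -> set:
    """Parse a GAF 2.1 file into a set of :class:`AnnotationRecord`.

    Lines starting ``!`` are headers/comments.  Each record line must have
    17 tab-separated columns; a wrong column count raises
    :class:`FormatError` naming the line.  An unparseable taxon field keeps
    the record with ``taxon`` unset and counts a warning.

    ``subject_kind`` is taken from GAF column 12 (DB Object Type):
    ``protein`` maps to protein-level records, anything else to gene-level.
    """
    records = set()
    for lineno, raw in enumerate(_as_lines(stream), 1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) != _GAF_NCOLS:
            raise FormatError(
                f"line {lineno}: expected {_GAF_NCOLS} tab-separated GAF "
                f"columns, found {len(cols)}"
            )
        object_type = cols[11]
        subject_kind = "protein" if object_type == "protein" else "gene"
        # normalize writer fallbacks so write(read(F)) round-trips both the
        # bytes and the record set: an empty symbol is written as the
        # subject id, an empty object_type as the subject kind's default
        symbol = "" if cols[2] == cols[1] else cols[2]
        if object_type == subject_kind:
            object_type = ""
        records.add(
            AnnotationRecord(
                db=cols[0],
                subject_id=cols[1],
                symbol=symbol,
                qualifier=cols[3],
                term=cols[4],
                db_reference=cols[5],
                evidence=cols[6],
                with_from=cols[7],
                aspect=cols[8] or None,
                object_name=cols[9],
                synonym=cols[10],
                object_type=object_type,
                subject_kind=subject_kind,
                taxon=_parse_taxon(cols[12], lineno, stats),
                date=cols[13],
                assigned_by=cols[14],
                extension=cols[15],
                gene_product_form=cols[16],
                source=source,
            )
        )
    return records


def gaf_line(record: AnnotationRecord) -> str:
    """Render one 17-column GAF 2.1 record line (no newline)."""
    if not record.subject_id or not record.term:
        raise FormatError(f"record missing subject or term: {record!r}")
    object_type = record.object_type or (
        "protein" if record.subject_kind == "protein" else "gene"
    )
    cols = [
        record.db,
        record.subject_id,
        record.symbol or record.subject_id,
        record.qualifier,
        record.term,
        record.db_reference,
        record.evidence,
        record.with_from,
        record.aspect or "",
        record.object_name,
        record.synonym,
        object_type,
        f"taxon:{record.taxon}" if record.taxon is not None else "",
        record.date,
        record.assigned_by,
        record.extension,
        record.gene_product_form,
    ]
    return "\t".join(cols)


def write_gaf(records: Iterable[AnnotationRecord], stream: IO[str]) -> None:
    """Write records as GAF 2.1, sorted by (subject, term, evidence) so
    output is deterministic.  Records that render to the same 17 columns
    (e.g. differing only in pipeline provenance, which GAF has no column
    for) emit a single line."""
    stream.write(GAF_VERSION_HEADER + "\n")
    for line in sorted(
        {gaf_line(r) for r in records},
        key=lambda l: (l.split("\t")[1], l.split("\t")[4], l.split("\t")[6], l),
    ):
        stream.write(line + "\n")


# ---------------------------------------------------------------------------
# UniProt idmapping


def read_idmapping(
    stream: Stream,
    protein_col: int = 1,
    gene_col: int = 3,
    stats: Optional[ParseStats] = None,
) -> IdMapping:
    """Parse a tab-separated protein->gene mapping table.

    Columns are 1-based, defaulting to the ``idmapping_selected.tab``
    layout (column 1 = UniProtKB-AC, column 3 = GeneID).  The gene column
    may hold semicolon-separated multiple gene ids; proteins with an empty
    gene field are omitted.  Multi-gene proteins are kept here — the
    exclusion rule is applied downstream by the UniProt ingest step.
    """
    mapping: dict = {}
    need = max(protein_col, gene_col)
    for lineno, raw in enumerate(_as_lines(stream), 1):
        line = raw.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < need:
            raise FormatError(
                f"line {lineno}: column index {need} out of range "
                f"(line has {len(cols)} columns)"
            )
        protein = cols[protein_col - 1].strip()
        genes = frozenset(
            g.strip() for g in cols[gene_col - 1].split(";") if g.strip()
        )
        if not protein or not genes:
            continue
        mapping[protein] = mapping.get(protein, frozenset()) | genes
    return IdMapping(protein_to_gene=mapping)


# ---------------------------------------------------------------------------
# InterProScan TSV


def _parse_go_field(value: str, lineno: int, stats: Optional[ParseStats]):
    value = value.strip()
    if not value or value == "-":
        return frozenset()
    terms = set()
    for token in value.split("|"):
        token = token.strip()
        # modern InterProScan may suffix the source, e.g. "GO:0005515(InterPro)"
        token = token.split("(")[0]
        if not token:
            continue
        if not GO_ID_RE.match(token):
            if stats is not None:
                stats.inc("interproscan_bad_go_id")
            continue
        terms.add(token)
    return frozenset(terms)


def read_interproscan(
    stream: Stream, stats: Optional[ParseStats] = None
) -> set:
    """Parse InterProScan TSV output into :class:`InterproRow` objects.

    Requires at least 11 columns per line; column 14, when present, holds
    pipe-separated GO ids (``-`` means none).
    """
    rows = set()
    for lineno, raw in enumerate(_as_lines(stream), 1):
        line = raw.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 11:
            raise FormatError(
                f"line {lineno}: InterProScan TSV needs at least 11 "
                f"columns, found {len(cols)}"
            )
        interpro = cols[11].strip() if len(cols) > 11 else ""
        rows.add(
            InterproRow(
                protein=cols[0],
                analysis=cols[3],
                signature=cols[4],
                interpro=interpro if interpro and interpro != "-" else None,
                go_terms=(
                    _parse_go_field(cols[13], lineno, stats)
                    if len(cols) > 13
                    else frozenset()
                ),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# 12-column tabular search results


def read_hits(stream: Stream, stats: Optional[ParseStats] = None) -> set:
    """Parse 12-column tabular pairwise-search output (outfmt 6 / -m 8)."""
    hits = set()
    for lineno, raw in enumerate(_as_lines(stream), 1):
        line = raw.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise FormatError(
                f"line {lineno}: expected 12 tab-separated columns, "
                f"found {len(cols)}"
            )
        try:
            hit = HitRow(
                query=cols[0],
                subject=cols[1],
                percent_identity=float(cols[2]),
                aln_length=int(cols[3]),
                mismatches=int(cols[4]),
                gap_opens=int(cols[5]),
                q_start=int(cols[6]),
                q_end=int(cols[7]),
                s_start=int(cols[8]),
                s_end=int(cols[9]),
                e_value=float(cols[10]),
                bit_score=float(cols[11]),
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric field: {exc}") from exc
        hits.add(hit)
    return hits


# ---------------------------------------------------------------------------
# GeneMerge association files


def write_genemerge(records: Iterable[AnnotationRecord], stream: IO[str]) -> None:
    """Write a GeneMerge association file: one line per gene with a
    semicolon-joined, sorted GO-term list.  NOT-qualified records are
    excluded."""
    by_gene: dict = {}
    for rec in records:
        if rec.is_negative:
            continue
        by_gene.setdefault(rec.subject_id, set()).add(rec.term)
    for gene in sorted(by_gene):
        stream.write(f"{gene}\t{';'.join(sorted(by_gene[gene]))}\n")
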