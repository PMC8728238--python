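"""Self-consistent synthetic fixture bundles with planted ground truth.

A bundle contains every input the annotation pipeline consumes — an OBO
ontology with random DAGs per aspect and cross-aspect links, a reference
proteome GAF, protein-to-gene tables, bidirectional hit tables, InterProScan
TSVs and a UniProt-style GAF plus idmapping — generated so that the correct
pipeline output is known by construction:

* planted orthologue pairs are mutual best hits whose bit scores are drawn
  strictly above the decoy range, so best-hit recovery is deterministic;
* a configurable fraction of non-orthologous query proteins get a
  non-reciprocal best hit with a domain profile copied verbatim from the
  reference protein (transfer expected) or deliberately perturbed
  (no transfer);
* a configurable number of UniProt proteins map to several genes, so the
  multi-gene exclusion counter is predictable.

No residue-level sequences are generated; hit tables are synthesized
directly.  One pseudo-random stream per file type, all derived from the
master seed, so adding a file type never perturbs existing fixtures and a
fixed seed yields a byte-identical bundle.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .formats_io import (
    AnnotationRecord,
    DEFAULT_GAF_DATE,
    write_gaf,
)
from .pipeline import PipelineConfig, PipelineResult, ReferenceSpec

_ASPECT_NS = (
    (1, "molecular_function"),
    (2, "biological_process"),
    (3, "cellular_component"),
)

#: Fixed spawn keys: one independent random stream per file type.
_STREAMS = {
    "ontology": 0,
    "reference": 1,
    "query": 2,
    "hits": 3,
    "domains": 4,
    "uniprot": 5,
}

_ANALYSES_CYCLE = ("Pfam", "SMART", "SUPERFAMILY", "PANTHER")


class FixtureSpecError(ValueError):
    """An infeasible fixture specification."""


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic bundle.

    Defaults are sized so a bundle generates in well under a second while
    still exercising every pipeline rule: three GO aspects of 30 terms
    each, 60 reference and 80 query genes, roughly half the query genes
    with a planted one-to-one orthologue, and half of the remaining
    best-hit pairs given identical domain profiles.
    """

    seed: int = 0
    n_terms_per_aspect: int = 30
    dag_density: float = 0.12
    n_ref_genes: int = 60
    n_query_genes: int = 80
    orthologue_fraction: float = 0.45
    domain_vocab_size: int = 40
    profile_match_fraction: float = 0.5
    human_mode: bool = False
    n_multi_gene_proteins: int = 3
    n_unmapped_uniprot: int = 2
    n_obsolete_per_aspect: int = 1
    n_alt_ids: int = 2
    taxon: int = 7460
    species: str = "synthsp"

    def __post_init__(self):
        for name in ("dag_density", "orthologue_fraction", "profile_match_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise FixtureSpecError(f"{name}={v} outside [0, 1]")
        if self.orthologue_fraction > 0 and self.n_ref_genes == 0:
            raise FixtureSpecError(
                "orthologue_fraction > 0 requires reference genes"
            )
        if self.n_terms_per_aspect < 3:
            raise FixtureSpecError("need at least 3 terms per aspect")

    @property
    def ref_name(self) -> str:
        return "human" if self.human_mode else "dmel"

    @property
    def ref_taxon(self) -> int:
        return 9606 if self.human_mode else 7227


@dataclass
class GroundTruth:
    """What the pipeline must recover from a bundle."""

    orthologue_pairs: set  # (query protein, reference protein)
    profile_match_pairs: set  # non-reciprocal best hits with equal profiles
    expected_transfer_terms: dict  # query gene -> frozenset of GO ids (pre-closure)
    expected_discards: dict
    ref_name: str
    human_mode: bool

    def to_dict(self) -> dict:
        return {
            "orthologue_pairs": sorted(map(list, self.orthologue_pairs)),
            "profile_match_pairs": sorted(map(list, self.profile_match_pairs)),
            "expected_transfer_terms": {
                g: sorted(ts) for g, ts in sorted(self.expected_transfer_terms.items())
            },
            "expected_discards": dict(sorted(self.expected_discards.items())),
            "ref_name": self.ref_name,
            "human_mode": self.human_mode,
        }


@dataclass
class Bundle:
    """Paths of one generated fixture bundle plus a ready-to-run config."""

    directory: str
    obo: str
    uniprot_gaf: str
    idmapping: str
    query_p2g: str
    query_interpro: str
    ref_gaf: str
    ref_p2g: str
    ref_interpro: str
    hits_fwd: str
    hits_rev: str
    config_path: str
    config: PipelineConfig
    spec: FixtureSpec


@dataclass
class RecoveryReport:
    passed: bool
    failures: list
    checks: dict


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# ontology generation


def _make_ontology(spec: FixtureSpec):
    """Random DAG per aspect (edges point from higher to lower rank, so the
    graph is acyclic by construction) plus cross-aspect link edges."""
    rng = _rng(spec.seed, "ontology")
    n = spec.n_terms_per_aspect
    terms: dict = {}  # id -> dict(name, namespace, obsolete, alt_ids)
    edges: list = []
    per_aspect_ids: dict = {}

    for digit, namespace in _ASPECT_NS:
        ids = [f"GO:{digit}{rank:06d}" for rank in range(n)]
        per_aspect_ids[namespace] = ids
        for rank, tid in enumerate(ids):
            terms[tid] = {
                "name": f"synthetic {namespace.replace('_', ' ')} term {rank}",
                "namespace": namespace,
                "obsolete": False,
                "alt_ids": [],
            }
            if rank >= 1:
                parent = ids[int(rng.integers(0, rank))]
                edges.append((tid, "is_a", parent))
        # extra forward edges
        for rank in range(2, n):
            for j in range(rank - 1):
                if rng.random() < spec.dag_density:
                    rel = "is_a" if rng.random() < 0.7 else "part_of"
                    edges.append((ids[rank], rel, ids[j]))
        for k in range(spec.n_obsolete_per_aspect):
            oid = f"GO:{digit}{n + k:06d}"
            terms[oid] = {
                "name": f"obsolete synthetic term {k}",
                "namespace": namespace,
                "obsolete": True,
                "alt_ids": [],
            }
        for k in range(min(spec.n_alt_ids, n - 1)):
            terms[ids[k + 1]]["alt_ids"].append(f"GO:{digit}9{k:05d}")

    # cross-aspect inter-ontology links: F --part_of--> P, P --occurs_in--> C
    n_cross = max(2, n // 8)
    mf, bp, cc = (per_aspect_ids[ns] for _, ns in _ASPECT_NS)
    for idx in sorted(rng.choice(np.arange(1, n), size=n_cross, replace=False)):
        edges.append((mf[int(idx)], "part_of", bp[int(rng.integers(1, n))]))
    for idx in sorted(rng.choice(np.arange(1, n), size=n_cross, replace=False)):
        edges.append((bp[int(idx)], "occurs_in", cc[int(rng.integers(1, n))]))

    edges = sorted(set(edges))
    usable = sorted(
        tid
        for tid, info in terms.items()
        if not info["obsolete"] and not tid.endswith("000000")
    )
    return terms, edges, usable


def _write_obo(path: str, terms: dict, edges: list) -> None:
    by_child: dict = {}
    for child, rel, parent in edges:
        by_child.setdefault(child, []).append((rel, parent))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("data-version: synthetic\n")
        fh.write("ontology: go-synthetic\n\n")
        for tid in sorted(terms):
            info = terms[tid]
            fh.write("[Term]\n")
            fh.write(f"id: {tid}\n")
            fh.write(f"name: {info['name']}\n")
            fh.write(f"namespace: {info['namespace']}\n")
            for alt in info["alt_ids"]:
                fh.write(f"alt_id: {alt}\n")
            if info["obsolete"]:
                fh.write("is_obsolete: true\n")
            for rel, parent in sorted(by_child.get(tid, [])):
                pname = terms[parent]["name"]
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {pname}\n")
                else:
                    fh.write(f"relationship: {rel} {parent} ! {pname}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# tabular helpers


def _hit_line(rng, query: str, subject: str, bit_lo: float, bit_hi: float,
              e_value: float) -> str:
    pid = rng.uniform(40.0, 99.0)
    alen = int(rng.integers(80, 400))
    mism = int(rng.integers(0, 40))
    gaps = int(rng.integers(0, 5))
    qs = int(rng.integers(1, 20))
    qe = qs + alen - 1
    ss = int(rng.integers(1, 20))
    se = ss + alen - 1
    bits = rng.uniform(bit_lo, bit_hi)
    return (
        f"{query}\t{subject}\t{pid:.2f}\t{alen}\t{mism}\t{gaps}\t"
        f"{qs}\t{qe}\t{ss}\t{se}\t{e_value:.1e}\t{bits:.1f}"
    )


def _interpro_rows(rng, protein: str, signatures, sig_analysis: dict,
                   sig_go: dict) -> list:
    rows = []
    for sig in sorted(signatures):
        go = "|".join(sorted(sig_go.get(sig, ()))) or "-"
        length = int(rng.integers(150, 900))
        start = int(rng.integers(1, 50))
        end = start + int(rng.integers(40, 120))
        rows.append(
            f"{protein}\t{'0' * 32}\t{length}\t{sig_analysis[sig]}\t{sig}\t"
            f"synthetic domain\t{start}\t{end}\t1.0E-10\tT\t{DEFAULT_GAF_DATE}\t"
            f"-\t-\t{go}"
        )
    return rows


# ---------------------------------------------------------------------------
# bundle generation


def make_bundle(spec: FixtureSpec, out_dir: str):
    """Generate the fixture bundle under ``out_dir``; returns
    ``(Bundle, GroundTruth)``.  Fixed seed implies a byte-identical bundle.
    """
    os.makedirs(out_dir, exist_ok=True)
    terms, edges, usable = _make_ontology(spec)
    term_aspect = {
        tid: {"molecular_function": "F", "biological_process": "P",
              "cellular_component": "C"}[info["namespace"]]
        for tid, info in terms.items()
    }
    obo_path = os.path.join(out_dir, "go.obo")
    _write_obo(obo_path, terms, edges)

    # ---- reference proteome and annotations
    rng_r = _rng(spec.seed, "reference")
    ref_proteins = [f"RP{i:05d}" for i in range(spec.n_ref_genes)]
    ref_genes = [f"RG{i:05d}" for i in range(spec.n_ref_genes)]
    ref_terms: dict = {}
    ref_records = set()
    for rp in ref_proteins:
        nt = int(rng_r.integers(1, 4))
        picked = sorted(
            usable[int(i)] for i in rng_r.choice(len(usable), nt, replace=False)
        )
        evidence = str(rng_r.choice(["EXP", "IDA", "ISS"]))
        ref_terms[rp] = picked
        for t in picked:
            ref_records.add(
                AnnotationRecord(
                    subject_id=rp,
                    subject_kind="protein",
                    term=t,
                    aspect=term_aspect[t],
                    evidence=evidence,
                    source="reference",
                    taxon=spec.ref_taxon,
                    assigned_by=spec.ref_name,
                    db="UniProtKB",
                    object_type="protein",
                )
            )
    if ref_proteins:
        # one NOT-qualified record, never to be transferred
        leftover = sorted(set(usable) - set(ref_terms[ref_proteins[0]]))
        not_term = leftover[int(rng_r.integers(0, len(leftover)))]
        ref_records.add(
            AnnotationRecord(
                subject_id=ref_proteins[0],
                subject_kind="protein",
                term=not_term,
                aspect=term_aspect[not_term],
                evidence="IDA",
                qualifier="NOT",
                source="reference",
                taxon=spec.ref_taxon,
                assigned_by=spec.ref_name,
                db="UniProtKB",
                object_type="protein",
            )
        )
    ref_gaf_path = os.path.join(out_dir, f"{spec.ref_name}.gaf")
    with open(ref_gaf_path, "w") as fh:
        write_gaf(ref_records, fh)
    ref_p2g_path = os.path.join(out_dir, f"{spec.ref_name}.p2g.tsv")
    with open(ref_p2g_path, "w") as fh:
        for rp, rg in zip(ref_proteins, ref_genes):
            fh.write(f"{rp}\t{rg}\n")

    # ---- query gene/protein structure
    rng_q = _rng(spec.seed, "query")
    query_genes = [f"QG{i:05d}" for i in range(spec.n_query_genes)]
    proteins_of_gene: dict = {}
    for i, qg in enumerate(query_genes):
        isoforms = [f"QP{i:05d}A"]
        if rng_q.random() < 0.12:
            isoforms.append(f"QP{i:05d}B")
        proteins_of_gene[qg] = isoforms
    gene_of_protein = {
        p: g for g, ps in proteins_of_gene.items() for p in ps
    }
    query_p2g_path = os.path.join(out_dir, "query.p2g.tsv")
    with open(query_p2g_path, "w") as fh:
        for qg in query_genes:
            for qp in proteins_of_gene[qg]:
                fh.write(f"{qp}\t{qg}\n")

    # ---- orthologue planting and hit tables
    rng_h = _rng(spec.seed, "hits")
    n_orth = int(round(spec.orthologue_fraction * spec.n_query_genes))
    n_orth = min(n_orth, spec.n_ref_genes)
    orth_gene_idx = sorted(
        int(i) for i in rng_h.choice(spec.n_query_genes, n_orth, replace=False)
    )
    partner_ref_idx = [
        int(i) for i in rng_h.choice(spec.n_ref_genes, n_orth, replace=False)
    ]
    orth_pairs = []
    for gi, ri in zip(orth_gene_idx, partner_ref_idx):
        orth_pairs.append(
            (proteins_of_gene[query_genes[gi]][0], ref_proteins[ri])
        )
    partner_refs = [r for _, r in orth_pairs]

    remaining = [query_genes[i] for i in range(spec.n_query_genes)
                 if i not in set(orth_gene_idx)]
    perm = rng_h.permutation(len(remaining))
    remaining = [remaining[int(i)] for i in perm]
    n_nohit = max(1, len(remaining) // 10) if remaining else 0
    nohit_genes = remaining[:n_nohit]
    besthit_genes = remaining[n_nohit:]
    n_match = int(round(spec.profile_match_fraction * len(besthit_genes)))
    match_genes = besthit_genes[:n_match]
    mismatch_genes = besthit_genes[n_match:]

    fwd_lines: list = []
    rev_lines: list = []
    n_over_threshold = 0

    for q, r in orth_pairs:
        ev = 10.0 ** -float(rng_h.uniform(50, 120))
        fwd_lines.append(_hit_line(rng_h, q, r, 300, 400, ev))
        rev_lines.append(_hit_line(rng_h, r, q, 300, 400, ev))
        for _ in range(int(rng_h.integers(1, 3))):  # low-scoring decoys
            other = ref_proteins[int(rng_h.integers(0, len(ref_proteins)))]
            if other != r:
                fwd_lines.append(_hit_line(rng_h, q, other, 50, 150, 1e-10))
        all_qp = sorted(gene_of_protein)
        other_q = all_qp[int(rng_h.integers(0, len(all_qp)))]
        if other_q != q:
            rev_lines.append(_hit_line(rng_h, r, other_q, 50, 150, 1e-10))

    best_hit_target: dict = {}  # non-reciprocal best-hit query protein -> ref
    sink = proteins_of_gene[nohit_genes[0]][0] if nohit_genes else None
    for j, qg in enumerate(besthit_genes):
        q = proteins_of_gene[qg][0]
        if partner_refs:
            r = partner_refs[j % len(partner_refs)]
        else:
            r = ref_proteins[j % len(ref_proteins)]
        best_hit_target[q] = r
        fwd_lines.append(_hit_line(rng_h, q, r, 180, 250, 1e-30))
        other = ref_proteins[int(rng_h.integers(0, len(ref_proteins)))]
        if other != r:
            fwd_lines.append(_hit_line(rng_h, q, other, 50, 150, 1e-10))
        # reverse hit exists but is never the reference protein's best
        rev_lines.append(_hit_line(rng_h, r, q, 60, 140, 1e-10))
        if not partner_refs and sink is not None:
            rev_lines.append(_hit_line(rng_h, r, sink, 300, 400, 1e-60))

    for qg in query_genes:
        for qp in proteins_of_gene[qg][1:]:
            # secondary isoforms only hit above the e-value cutoff
            r = ref_proteins[int(rng_h.integers(0, len(ref_proteins)))] if ref_proteins else None
            if r is not None:
                fwd_lines.append(_hit_line(rng_h, qp, r, 60, 90, 5e-3))
                n_over_threshold += 1

    hits_fwd_path = os.path.join(out_dir, f"query_vs_{spec.ref_name}.tsv")
    hits_rev_path = os.path.join(out_dir, f"{spec.ref_name}_vs_query.tsv")
    with open(hits_fwd_path, "w") as fh:
        fh.write("\n".join(fwd_lines) + ("\n" if fwd_lines else ""))
    with open(hits_rev_path, "w") as fh:
        fh.write("\n".join(rev_lines) + ("\n" if rev_lines else ""))

    # ---- domain vocabulary, profiles, InterProScan TSVs
    rng_d = _rng(spec.seed, "domains")
    vocab = [f"SIG{i:05d}" for i in range(spec.domain_vocab_size)]
    sig_analysis = {
        sig: _ANALYSES_CYCLE[i % len(_ANALYSES_CYCLE)]
        for i, sig in enumerate(vocab)
    }
    sig_go: dict = {}
    for sig in vocab:
        if rng_d.random() < 0.5:
            k = int(rng_d.integers(1, 3))
            sig_go[sig] = sorted(
                usable[int(i)] for i in rng_d.choice(len(usable), k, replace=False)
            )

    ref_profile: dict = {}
    for rp in ref_proteins:
        k = int(rng_d.integers(1, 4))
        ref_profile[rp] = frozenset(
            vocab[int(i)] for i in rng_d.choice(len(vocab), k, replace=False)
        )

    match_proteins = {proteins_of_gene[g][0] for g in match_genes}
    query_profile: dict = {}
    for qg in query_genes:
        for qp in proteins_of_gene[qg]:
            if qp in match_proteins:
                query_profile[qp] = ref_profile[best_hit_target[qp]]
                continue
            k = int(rng_d.integers(0, 4))
            prof = frozenset(
                vocab[int(i)] for i in rng_d.choice(len(vocab), k, replace=False)
            )
            target = best_hit_target.get(qp)
            if target is not None:
                while prof == ref_profile[target]:
                    extra = sorted(set(vocab) - ref_profile[target])
                    prof = prof | {extra[int(rng_d.integers(0, len(extra)))]}
            query_profile[qp] = prof

    def write_interpro(path: str, profiles: dict) -> None:
        lines: list = []
        for i, protein in enumerate(sorted(profiles)):
            lines.extend(
                _interpro_rows(rng_d, protein, profiles[protein],
                               sig_analysis, sig_go)
            )
            if i < 2:  # excluded analysis, exercises profile filtering
                lines.append(
                    f"{protein}\t{'0' * 32}\t300\tCoils\tCoil\t"
                    f"coiled-coil\t5\t40\t-\tT\t{DEFAULT_GAF_DATE}\t-\t-\t-"
                )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))

    query_interpro_path = os.path.join(out_dir, "query.interpro.tsv")
    ref_interpro_path = os.path.join(out_dir, f"{spec.ref_name}.interpro.tsv")
    write_interpro(query_interpro_path, query_profile)
    write_interpro(ref_interpro_path, ref_profile)

    # ---- UniProt-GOA style GAF and idmapping
    rng_u = _rng(spec.seed, "uniprot")
    n_uni = max(4, spec.n_query_genes // 5)
    uni_records = set()
    idmap_lines: list = []

    def uni_record(acc: str, term: str, qualifier: str = "") -> AnnotationRecord:
        return AnnotationRecord(
            subject_id=acc,
            subject_kind="protein",
            term=term,
            aspect=term_aspect[term],
            evidence="IDA",
            qualifier=qualifier,
            source="uniprot",
            taxon=spec.taxon,
            assigned_by="UniProt",
            db="UniProtKB",
            object_type="protein",
        )

    for i in range(n_uni):
        acc = f"UPQ{i:05d}"
        gene = query_genes[int(rng_u.integers(0, len(query_genes)))]
        idmap_lines.append(f"{acc}\t{acc}_SYN\t{gene}")
        for _ in range(int(rng_u.integers(1, 3))):
            uni_records.add(
                uni_record(acc, usable[int(rng_u.integers(0, len(usable)))])
            )
    for i in range(spec.n_multi_gene_proteins):
        acc = f"UPM{i:05d}"
        g1, g2 = (
            query_genes[int(j)]
            for j in rng_u.choice(len(query_genes), 2, replace=False)
        )
        idmap_lines.append(f"{acc}\t{acc}_SYN\t{g1}; {g2}")
        uni_records.add(
            uni_record(acc, usable[int(rng_u.integers(0, len(usable)))])
        )
    for i in range(spec.n_unmapped_uniprot):
        acc = f"UPX{i:05d}"
        uni_records.add(
            uni_record(acc, usable[int(rng_u.integers(0, len(usable)))])
        )

    uniprot_gaf_path = os.path.join(out_dir, "uniprot.gaf")
    with open(uniprot_gaf_path, "w") as fh:
        write_gaf(uni_records, fh)
    idmapping_path = os.path.join(out_dir, "idmapping.tab")
    with open(idmapping_path, "w") as fh:
        fh.write("\n".join(idmap_lines) + ("\n" if idmap_lines else ""))

    # ---- pipeline config
    config = PipelineConfig(
        species=spec.species,
        taxon=spec.taxon,
        ontology=obo_path,
        out_dir=os.path.join(out_dir, "out"),
        uniprot_gaf=uniprot_gaf_path,
        idmapping=idmapping_path,
        idmapping_protein_col=1,
        idmapping_gene_col=3,
        interproscan=query_interpro_path,
        protein_to_gene=query_p2g_path,
        references=[
            ReferenceSpec(
                name=spec.ref_name,
                gaf=ref_gaf_path,
                protein_to_gene=ref_p2g_path,
                interproscan=ref_interpro_path,
                hits_fwd=hits_fwd_path,
                hits_rev=hits_rev_path,
                is_human=spec.human_mode,
            )
        ],
        gene_prefix="QG",
        seed=spec.seed,
    )
    config_path = os.path.join(out_dir, "config.yaml")
    config.to_yaml(config_path)

    # ---- ground truth
    expected: dict = {}
    for q, r in orth_pairs + [(q, r) for q, r in sorted(best_hit_target.items())
                              if q in match_proteins]:
        gene = gene_of_protein[q]
        terms_r = {
            t for t in ref_terms[r]
            if not (spec.human_mode and term_aspect[t] == "P")
        }
        expected[gene] = frozenset(expected.get(gene, frozenset()) | terms_r)
    truth = GroundTruth(
        orthologue_pairs=set(orth_pairs),
        profile_match_pairs={
            (q, r) for q, r in best_hit_target.items() if q in match_proteins
        },
        expected_transfer_terms=expected,
        expected_discards={
            "uniprot_multi_gene_proteins": spec.n_multi_gene_proteins,
            "uniprot_unmapped_proteins": spec.n_unmapped_uniprot,
            "hits_over_evalue": n_over_threshold,
        },
        ref_name=spec.ref_name,
        human_mode=spec.human_mode,
    )
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
        fh.write("\n")

    bundle = Bundle(
        directory=out_dir,
        obo=obo_path,
        uniprot_gaf=uniprot_gaf_path,
        idmapping=idmapping_path,
        query_p2g=query_p2g_path,
        query_interpro=query_interpro_path,
        ref_gaf=ref_gaf_path,
        ref_p2g=ref_p2g_path,
        ref_interpro=ref_interpro_path,
        hits_fwd=hits_fwd_path,
        hits_rev=hits_rev_path,
        config_path=config_path,
        config=config,
        spec=spec,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# recovery verification


def verify_recovery(truth: GroundTruth, result: PipelineResult) -> RecoveryReport:
    """Check pipeline output against the planted ground truth.

    (a) the recovered reciprocal-best-hit set equals the planted pairs;
    (b) each planted query gene carries exactly its expected transferred
        terms (source ``homology:<ref>``) and all their ancestors appear in
        the gene's closed term set;
    (c) a human-mode bundle contains zero transferred aspect-P records;
    (d) discard counters match the planted counts.
    """
    failures: list = []
    checks: dict = {}
    source = f"homology:{truth.ref_name}"

    got_rbh = result.rbh.get(truth.ref_name, set())
    checks["rbh_pairs"] = got_rbh == truth.orthologue_pairs
    if not checks["rbh_pairs"]:
        missing = sorted(truth.orthologue_pairs - got_rbh)[:5]
        spurious = sorted(got_rbh - truth.orthologue_pairs)[:5]
        failures.append(
            f"RBH mismatch: missing {missing}, spurious {spurious}"
        )

    observed: dict = {}
    gene_terms: dict = {}
    for rec in result.records:
        gene_terms.setdefault(rec.subject_id, set()).add(rec.term)
        if rec.source == source:
            observed.setdefault(rec.subject_id, set()).add(rec.term)
    expected = {
        g: set(ts) for g, ts in truth.expected_transfer_terms.items() if ts
    }
    checks["transferred_terms"] = observed == expected
    if not checks["transferred_terms"]:
        for g in sorted(set(observed) ^ set(expected))[:5]:
            failures.append(
                f"gene {g}: transferred {sorted(observed.get(g, ()))} "
                f"vs expected {sorted(expected.get(g, ()))}"
            )
        for g in sorted(set(observed) & set(expected)):
            if observed[g] != expected[g]:
                failures.append(
                    f"gene {g}: transferred {sorted(observed[g])} "
                    f"vs expected {sorted(expected[g])}"
                )

    ancestors_ok = True
    for gene, ts in expected.items():
        have = gene_terms.get(gene, set())
        for t in ts:
            anc = result.graph.ancestors(t)
            if not anc <= have:
                ancestors_ok = False
                failures.append(
                    f"gene {gene}: ancestors of {t} missing from closed set: "
                    f"{sorted(anc - have)[:5]}"
                )
    checks["ancestor_closure"] = ancestors_ok

    if truth.human_mode:
        bp = [
            rec
            for rec in result.records
            if rec.source.startswith("homology:") and rec.aspect == "P"
        ]
        checks["no_human_bp_transfers"] = not bp
        if bp:
            failures.append(
                f"{len(bp)} aspect-P records transferred from human reference"
            )

    disc_ok = True
    for key, want in truth.expected_discards.items():
        got = result.summary.discards.get(key, 0)
        if got != want:
            disc_ok = False
            failures.append(f"discard counter {key}: got {got}, want {want}")
    checks["discard_counters"] = disc_ok

    return RecoveryReport(passed=not failures, failures=failures, checks=checks)
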