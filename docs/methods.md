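# Methods

## Annotation model

A gene's GO annotation set is assembled from three sources and then closed
over the ontology.  The unit throughout is the `AnnotationRecord`: one
subject (gene or protein) × GO term assertion carrying aspect, evidence
code, qualifier and a provenance tag (`uniprot`, `interpro`,
`homology:<ref>`, `inter-ontology`, `closure`).  Records are deduplicated
on the key *(subject, kind, qualifier, term, evidence, source)*; records
that differ only in their supporting identifier (`with_from`) collapse
into one record with the identifiers joined by `|`.  Keeping `source` in
the key preserves parallel records per gene–term pair so provenance stays
auditable; GAF permits multiple records per gene and term.

NOT-qualified records are parsed but excluded from every transfer and
merge step.  Transferring negative annotations by homology is unsound, and
positive enrichment sets must not silently absorb them.

### Stage order

sources → merge → inter-ontology inference → ancestor closure.

Inference runs before closure so inferred annotations also receive their
ancestors.  Closure is idempotent: closure-generated records carry an
empty `with_from`, so re-closing a closed set reproduces it exactly rather
than accumulating joined child pointers.

### Curated source

Protein-level records are re-subjected to genes through an
`idmapping_selected.tab`-style table (defaults: column 1 = accession,
column 3 = gene id; both configurable since upstream databases differ in
which accession namespace they key on).  A protein mapping to more than
one gene contributes nothing — assigning a curated annotation to an
arbitrary one of several genes would fabricate gene-level evidence.  Both
discard classes (multi-gene, unmapped) are counted per distinct protein.

### Domain source

Every (protein, GO id) pair in InterProScan TSV output yields one
gene-level record with evidence IEA and the matching signature accession
in `with_from`.  The GO column is taken as pipe-separated ids; a trailing
`(source)` suffix, as newer InterProScan versions emit, is stripped.

### Homology source

Best hit = maximal bit score, ties broken by minimal e-value then by
lexicographically smallest subject id — bit score is the standard
criterion and the two tie-breaks make selection total and deterministic.
Hits with e-value above the cutoff (default 1 × 10⁻⁵, a conventional
protein-homology threshold; configurable) are removed before selection.

Transfers happen for reciprocal best hits, and for non-reciprocal best
hits whose domain content is identical.  Domain content is the *set* of
signature accessions from the SMART, SUPERFAMILY, PANTHER and Pfam
analyses (configurable); equality ignores copy number and order, and
granularity at the InterPro-entry level can be obtained by supplying those
accessions instead.  Query isoforms are searched per protein; transfers
collapse to genes as the union over a gene's proteins — the only monotone
choice when isoforms hit different references.

From a human reference, biological-process terms are withheld: molecular
function and cellular component transfer more reliably across large
evolutionary distances than process membership.  All computed transfers
carry evidence IEA, the GO convention for unreviewed computational
assignments.

## Ontology handling

The OBO parser supports the tag subset the pipeline needs (`id`, `name`,
`namespace`, `alt_id`, `is_a`, `relationship`, `is_obsolete`); it is
deliberately not a full OBO 1.2 implementation (no `intersection_of`, no
imports).  Obsolete terms are recorded but carry no edges; annotations to
them are dropped and counted rather than remapped via `replaced_by` —
conservative, no guessing.  `alt_id` lookups resolve silently to the
primary id with a counter.

Closure relations default to `{is_a, part_of}`, the standard true-path
propagation set; the set is configurable because reasonable pipelines
differ on `part_of`.  The closure-relation subgraph is validated acyclic
at load; a violation reports one concrete cycle.

Inter-ontology inference channels default to F→P via `part_of` and P→C
via `occurs_in`, the documented GO inter-ontology link classes; the
channel set is configurable.  Only direct link edges seed inference —
transitive propagation is closure's job and runs afterwards.

## Enrichment

Exact upper-tail hypergeometric test per term (scipy), over
ancestor-closed gene-level annotations.  Unannotated background genes
count in N (the GeneMerge population convention; conventions differ, so
this is stated rather than assumed).  Tested terms are those with K ≥ 1
and k ≥ 1; the correction denominator is the number of tested terms.
Bonferroni is the default (matching GeneMerge); Benjamini–Hochberg is
available.  Under-representation (lower tail) sits behind a flag.
p-values are clamped into (0, 1] against floating-point underflow on
extreme instances.

## Synthetic fixtures: what they emulate, and what not

`synthfix` generates the study conditions for every test: random DAGs per
aspect built by ranking terms and adding only rank-decreasing edges
(acyclic by construction), cross-aspect link edges, a reference proteome
with 1–3 annotations per protein plus one NOT-qualified record, a query
species with occasional two-isoform genes, bidirectional hit tables, and
InterProScan TSVs realizing planted profile equalities.

Defaults: 30 terms per aspect (edge probability 0.12), 60 reference and
80 query genes, orthologue fraction 0.45, profile-match fraction 0.5,
domain vocabulary 40 signatures, 3 multi-gene and 2 unmapped UniProt
proteins — large enough that every rule fires many times per bundle,
small enough that a bundle generates and runs in well under a second.
Planted orthologues get bit scores drawn from 300–400 while decoys stay in
50–150, so best-hit recovery is deterministic and a recovery failure
isolates a logic error rather than sampling noise.  Non-reciprocal best
hits score 180–250 with the reverse direction dominated by the reference
protein's own partner (or a designated sink protein), so reciprocity can
never arise by accident.  Secondary isoforms only receive hits above the
e-value cutoff, which exercises the over-threshold counter.  One random
stream per file type, all derived from the master seed via fixed spawn
keys: adding a file type never perturbs existing fixtures, and a fixed
seed yields a byte-identical bundle.

What the fixtures do **not** emulate: residue-level sequences and real
alignment-score distributions (hit tables are synthesized directly),
paralogy and one-to-many orthology, annotation-bias structure in real
GOA releases, and GO's actual term-frequency skew.  Passing tests
therefore demonstrate that the *rules* are implemented correctly under
controlled conditions, not that transfer quality on real proteomes meets
any accuracy target.

## Numerical and determinism choices

* All writers sort their output (GAF by subject/term/evidence, GeneMerge
  by gene, edge exports lexicographically) and record lines contain a
  fixed date, never a timestamp, so identical inputs give byte-identical
  outputs.
* Identical rendered GAF lines are emitted once even when several records
  (differing only in pipeline provenance, which GAF has no column for)
  produce them.
* Best-hit selection, tie-breaks, dedup representatives and merge order
  are all defined totals — no dict-order or set-order dependence reaches
  an output file.
* Pipeline stage errors abort with the stage name and remove partial
  outputs.

## Known limitations

* GAF dialect is fixed at 2.1 (17 columns); GAF 2.2/GPAD qualifiers are
  out of scope.
* Streaming performance on production-scale `goa_uniprot_all` files is
  untuned; readers are line-based and memory-proportional to the record
  count.
* Orthology resolution stops at best hits; no cluster-level or
  one-to-many reasoning.
* Enrichment is the classical independent-term test; topology-aware
  methods (elim/weight) and ranked (GSEA-style) tests are non-goals.
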