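"""GO over-representation analysis with the exact hypergeometric test.

Given a study gene list drawn from a background (population) universe and
ancestor-closed annotations, each GO term observed in both study and
background is tested: with N background genes, K of them annotated to the
term, a study of n genes containing k annotated ones, the upper-tail
probability is

    p_raw = sum_{i=k}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n)

Unannotated background genes count in N (the GeneMerge population
convention).  Correction is over the number of tested terms (K >= 1 and
k >= 1); Bonferroni by default, Benjamini-Hochberg available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

METHODS = {"bonferroni": "bonferroni", "bh": "fdr_bh"}


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    N: int  # background size (genes)
    K: int  # background genes annotated to term
    n: int  # study size
    k: int  # study genes annotated to term
    p_raw: float
    p_corrected: float
    method: str
    name: str = ""
    aspect: Optional[str] = None


def correct(p_values: Sequence[float], method: str = "bonferroni") -> list:
    """Multiple-testing correction.

    ``bonferroni``: min(1, p * m).  ``bh``: Benjamini-Hochberg step-up
    adjusted values, monotone non-decreasing in rank.
    """
    if method not in METHODS:
        raise ValueError(
            f"unknown correction method {method!r}; choose from "
            f"{sorted(METHODS)}"
        )
    p_values = list(p_values)
    if not p_values:
        return []
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    return list(multipletests(p_values, method=METHODS[method])[1])


def annotation_index(records: Iterable) -> dict:
    """Gene -> set of GO terms, excluding NOT-qualified records."""
    index: dict = {}
    for rec in records:
        if rec.is_negative:
            continue
        index.setdefault(rec.subject_id, set()).add(rec.term)
    return index


def enrich(
    study: Iterable[str],
    background: Iterable[str],
    records: Iterable,
    graph=None,
    method: str = "bonferroni",
    direction: str = "over",
) -> list:
    """Test every GO term for over-representation in the study list.

    ``records`` should be gene-level annotations already closed under
    ancestors so the true-path rule holds for the counts.  Terms with
    K >= 1 and k >= 1 are tested; results are sorted by corrected p-value,
    ties broken by term id.  ``direction="under"`` tests depletion
    (lower tail) instead.
    """
    study = set(study)
    background = set(background)
    if not study:
        raise ValueError("study set is empty")
    stray = study - background
    if stray:
        raise ValueError(
            "study genes missing from background: " + ", ".join(sorted(stray))
        )
    if direction not in ("over", "under"):
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")

    index = annotation_index(records)
    term_background: dict = {}
    term_study: dict = {}
    for gene in background:
        for term in index.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    N, n = len(background), len(study)
    tested = sorted(t for t in term_study if term_study[t] >= 1)
    raw = []
    for term in tested:
        K, k = term_background[term], term_study[term]
        if direction == "over":
            p = float(hypergeom.sf(k - 1, N, K, n))
        else:
            p = float(hypergeom.cdf(k, N, K, n))
        # clamp into (0, 1]: the exact probability is positive whenever
        # k >= 1, but extreme instances can underflow to 0.0
        raw.append(min(1.0, max(p, 1e-300)))

    corrected = correct(raw, method=method) if raw else []
    results = []
    for term, p, pc in zip(tested, raw, corrected):
        name, aspect = "", None
        if graph is not None and term in graph:
            primary = graph.resolve(term)
            name = graph.terms[primary].name
            aspect = graph.aspect_of(primary)
        results.append(
            EnrichmentResult(
                term=term,
                N=N,
                K=term_background[term],
                n=n,
                k=term_study[term],
                p_raw=p,
                p_corrected=float(pc),
                method=method,
                name=name,
                aspect=aspect,
            )
        )
    results.sort(key=lambda r: (r.p_corrected, r.term))
    return results


def write_enrichment_tsv(results: Iterable[EnrichmentResult], stream: IO[str]) -> None:
    """TSV result table: term, name, aspect, N, K, n, k, p_raw, p_corrected."""
    stream.write("term\tname\taspect\tN\tK\tn\tk\tp_raw\tp_corrected\n")
    for r in results:
        stream.write(
            f"{r.term}\t{r.name}\t{r.aspect or ''}\t{r.N}\t{r.K}\t{r.n}\t"
            f"{r.k}\t{r.p_raw:.6g}\t{r.p_corrected:.6g}\n"
        )
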