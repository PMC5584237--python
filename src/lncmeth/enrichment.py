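"""Cis-regulatory assignment, set enrichment and the GO term network.

Cis regulation is approximated by a transparent nearest-gene rule
(each lncRNA is assigned to the protein-coding gene whose TSS is
closest, within a distance cap) followed by gene-level hypergeometric
enrichment with Benjamini-Hochberg FDR; this is a deliberately simple,
auditable stand-in for web-service region-enrichment tools.  miRNA-
disease enrichment uses the same hypergeometric tail at a raw p < 0.05
cutoff.  Significant terms are linked through their ``is_a`` relations
into a term graph whose connected components group related functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "nearest_gene",
    "hypergeom_p",
    "enrich",
    "mirna_disease_enrich",
    "gene_term_frequency",
    "build_term_graph",
]


@dataclass
class EnrichmentResult:
    """One tested term/disease with its contingency counts."""

    term_id: str
    term_name: str
    universe: int  # N
    annotated: int  # M, members of the term
    query: int  # n
    overlap: int  # m
    p: float
    fdr: float
    genes: tuple[str, ...] = ()


def nearest_gene(
    lncrnas: list[AnnotationRecord],
    genes: list[AnnotationRecord],
    max_distance: int = 1_000_000,
) -> dict[str, str | None]:
    """Map each lncRNA to the gene with minimal |gene TSS - lncRNA TSS|
    on the same chromosome, within ``max_distance``; unmapped lncRNAs
    get ``None``.  Equidistant candidates resolve to the smaller TSS
    coordinate (logged)."""
    if not genes:
        raise ValueError("empty gene annotation")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.feature_id))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    out: dict[str, str | None] = {}
    for lnc in lncrnas:
        cands = by_chrom.get(lnc.chrom)
        if not cands:
            out[lnc.feature_id] = None
            continue
        pos = np.array([c[0] for c in cands])
        i = int(np.searchsorted(pos, lnc.tss))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(cands):
                dist = abs(cands[j][0] - lnc.tss)
                if best is None or dist < best[0] or (dist == best[0] and cands[j][0] < best[2]):
                    if best is not None and dist == best[0]:
                        logger.info("nearest_gene: tie at %s broken toward smaller coordinate",
                                    lnc.feature_id)
                    best = (dist, cands[j][1], cands[j][0])
        out[lnc.feature_id] = best[1] if best and best[0] <= max_distance else None
    return out


def hypergeom_p(universe: int, annotated: int, query: int, overlap: int) -> float:
    """Upper-tail hypergeometric probability of an overlap >= m between
    a term of M members and a query of n, drawn from a universe of N:

        P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M, n-i) / C(N, n).
    """
    if not (0 <= overlap <= min(annotated, query) and annotated <= universe and query <= universe):
        raise ValueError(
            f"inconsistent counts: N={universe}, M={annotated}, n={query}, m={overlap}"
        )
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, annotated, query))


def enrich(
    query_genes,
    term_table: pd.DataFrame,
    universe,
    fdr_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a gene set against a term -> gene
    table (columns ``term_id``, ``term_name``, ``gene``), with BH FDR
    over all tested terms.  Returns all terms sorted by p; callers
    filter on ``fdr <= fdr_threshold`` (also flagged via the threshold
    argument for convenience: results list is unfiltered)."""
    universe = set(universe)
    query = set(query_genes) & universe
    big_n, n = len(universe), len(query)
    rows = []
    for (tid, tname), sub in sorted(term_table.groupby(["term_id", "term_name"], sort=True)):
        members = set(sub["gene"]) & universe
        overlap = sorted(query & members)
        rows.append((tid, tname, len(members), overlap))
    if not rows:
        return []
    pvals = np.array([hypergeom_p(big_n, m_count, n, len(ov)) for _, _, m_count, ov in rows])
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(tid, tname, big_n, m_count, n, len(ov), float(p), float(f),
                         genes=tuple(ov))
        for (tid, tname, m_count, ov), p, f in zip(rows, pvals, fdr)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def mirna_disease_enrich(
    mirna_set,
    disease_table: pd.DataFrame,
    p_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of a miRNA set against a disease ->
    miRNA annotation table (columns ``disease``, ``mirna_id``).

    The universe N is the total number of distinct annotated miRNAs;
    significance is judged on the raw p (< ``p_threshold``), without
    multiplicity adjustment.  ``fdr`` echoes the raw p."""
    universe = set(disease_table["mirna_id"])
    query = set(mirna_set) & universe
    results = []
    for disease, sub in sorted(disease_table.groupby("disease", sort=True)):
        members = set(sub["mirna_id"])
        overlap = sorted(query & members)
        p = hypergeom_p(len(universe), len(members), len(query), len(overlap))
        results.append(
            EnrichmentResult(disease, disease, len(universe), len(members),
                             len(query), len(overlap), p, p, genes=tuple(overlap))
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def gene_term_frequency(results: list[EnrichmentResult], fdr_threshold: float = 0.05) -> pd.Series:
    """Count, per gene, the significant terms containing it; sorted by
    descending count, ties by gene id."""
    counts: dict[str, int] = {}
    for r in results:
        if r.fdr <= fdr_threshold:
            for g in r.genes:
                counts[g] = counts.get(g, 0) + 1
    s = pd.Series(counts, dtype=int, name="n_terms")
    s.index.name = "gene"
    return s.sort_index().sort_values(ascending=False, kind="mergesort")


def build_term_graph(significant_terms, is_a_edges: pd.DataFrame) -> tuple[nx.DiGraph, list[set[str]]]:
    """Directed ``is_a`` graph induced on the significant terms, plus
    its weakly connected components (every term appears in exactly one
    component; isolated terms are singleton components)."""
    terms = set(significant_terms)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(terms))
    for child, parent in zip(is_a_edges["child"], is_a_edges["parent"]):
        if child in terms and parent in terms:
            g.add_edge(child, parent)
    components = sorted(nx.weakly_connected_components(g), key=lambda c: (-len(c), min(c)))
    return g, components
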