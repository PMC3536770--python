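"""Hypergeometric GO term enrichment with redundancy filtering.

Over/under-representation of GO terms in an expression cluster is tested with
the exact hypergeometric distribution against the universe of well-measured
genes.  Annotations follow the true-path rule (genes propagate to all
ancestors before testing).  Closely related enriched terms are pruned with an
OSIR-style redundancy filter: a term's Ontology Specific Information Rate is
1 minus the largest fraction of its (cluster-restricted) genes shared with a
retained enriched ancestor or descendant; terms below the cutoff are dropped,
keeping the smallest-p member of each redundant set.  Reported terms must
additionally pass a fixed p-value cutoff and a minimum gene count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
from scipy import stats

from .errors import InvalidInputError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One term's enrichment against one cluster."""

    term: str
    observed: int
    expected: float
    universe_size: int
    term_size: int
    cluster_size: int
    p_over: float
    p_under: float
    osir: float | None = None
    retained: bool = True  # survived the OSIR filter
    reported: bool = False

    @property
    def cluster_genes_in_term(self) -> int:
        return self.observed


def hypergeom_test(
    cluster_genes: Iterable, term_genes: Iterable, universe: Iterable
) -> tuple[float, float]:
    """Exact hypergeometric tails for the cluster/term overlap.

    p_over = P(X >= observed), p_under = P(X <= observed), where X counts term
    genes among |cluster| draws without replacement from the universe.
    """
    universe = set(universe)
    if not universe:
        raise InvalidInputError("universe must be non-empty")
    cluster = set(cluster_genes)
    term = set(term_genes)
    if not cluster <= universe or not term <= universe:
        raise InvalidInputError("cluster and term must be subsets of the universe")
    M, n, N = len(universe), len(term), len(cluster)
    x = len(cluster & term)
    p_over = float(stats.hypergeom.sf(x - 1, M, n, N))
    p_under = float(stats.hypergeom.cdf(x, M, n, N))
    return p_over, p_under


def propagate_annotations(
    annotations: Mapping[str, set], dag: nx.DiGraph
) -> dict[str, set]:
    """True-path rule: each term also carries the genes of its descendants.

    ``dag`` edges point parent -> child.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise InvalidInputError("ontology graph contains a cycle")
    out: dict[str, set] = {}
    for term in dag.nodes:
        genes = set(annotations.get(term, set()))
        for child in nx.descendants(dag, term):
            genes |= set(annotations.get(child, set()))
        out[term] = genes
    return out


def enrich_cluster(
    cluster_genes: set,
    annotations: Mapping[str, set],
    universe: set,
    dag: nx.DiGraph | None = None,
    propagate: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric test of every annotated term against one cluster."""
    if dag is not None and propagate:
        annotations = propagate_annotations(annotations, dag)
    results = []
    for term, genes in annotations.items():
        genes = set(genes) & universe
        if not genes:
            continue
        p_over, p_under = hypergeom_test(cluster_genes, genes, universe)
        observed = len(cluster_genes & genes)
        results.append(
            EnrichmentResult(
                term=term,
                observed=observed,
                expected=len(genes) * len(cluster_genes) / len(universe),
                universe_size=len(universe),
                term_size=len(genes),
                cluster_size=len(cluster_genes),
                p_over=p_over,
                p_under=p_under,
            )
        )
    return results


def osir_filter(
    results: list[EnrichmentResult],
    dag: nx.DiGraph,
    annotations: Mapping[str, set],
    cluster_genes: set,
    cutoff: float = 0.95,
    enriched_p: float = 1e-6,
) -> list[EnrichmentResult]:
    """Prune redundant enriched terms; returns the retained enriched subset.

    Enriched terms (p_over <= enriched_p) are visited in ascending-p order.
    For each, OSIR = 1 - max over already-retained enriched ancestors or
    descendants of the shared fraction of its cluster-restricted gene set;
    the term is kept iff OSIR >= cutoff, so among mutually redundant terms
    the smallest-p one survives.  Every result's ``osir``/``retained`` fields
    are filled in; non-enriched terms are left retained (the filter only
    arbitrates between enriched relatives).
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise InvalidInputError("ontology graph contains a cycle")
    enriched = sorted(
        (r for r in results if r.p_over <= enriched_p),
        key=lambda r: (r.p_over, r.term),
    )
    relatives = {
        r.term: (nx.ancestors(dag, r.term) | nx.descendants(dag, r.term))
        if r.term in dag
        else set()
        for r in enriched
    }
    cluster_sets = {
        r.term: set(annotations.get(r.term, set())) & cluster_genes for r in enriched
    }
    kept: list[EnrichmentResult] = []
    kept_terms: set[str] = set()
    for r in enriched:
        mine = cluster_sets[r.term]
        overlap = 0.0
        if mine:
            for other in relatives[r.term] & kept_terms:
                shared = len(mine & cluster_sets[other]) / len(mine)
                overlap = max(overlap, shared)
        else:
            overlap = 1.0  # no cluster genes of its own: fully redundant
        r.osir = 1.0 - overlap if mine else 0.0
        r.retained = r.osir >= cutoff
        if r.retained:
            kept.append(r)
            kept_terms.add(r.term)
    for r in results:
        if r.osir is None:
            r.osir = 1.0
            r.retained = True
    return kept


def report_enriched(
    results: list[EnrichmentResult],
    p_cutoff: float = 1e-6,
    min_genes: int = 3,
) -> list[EnrichmentResult]:
    """Flag terms as reported: p_over <= cutoff, >= min_genes observed, OSIR-retained."""
    reported = []
    for r in results:
        r.reported = r.p_over <= p_cutoff and r.observed >= min_genes and r.retained
        if r.reported:
            reported.append(r)
    logger.info("report_enriched: %d of %d terms reported", len(reported), len(results))
    return reported
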