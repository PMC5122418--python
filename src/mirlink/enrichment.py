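"""Ontology enrichment with the elim variant of Fisher's exact test.

Classic term-by-term Fisher enrichment inherits signal up the DAG: every
ancestor of a truly enriched term looks enriched too.  The elim
procedure counters this by testing the most specific terms first and,
whenever a term comes out significant, removing its annotated genes
from all of its ancestors before those are tested.

Each term is scored with the one-sided hypergeometric upper tail
P(X >= k) for k study hits among n study genes, K annotated genes in a
background of M.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .ontology import OntologyDag

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "EnrichmentProfile",
    "build_annotation_map",
    "fisher_enrich_term",
    "elim_enrich",
    "classic_enrich",
]


@dataclass
class AnnotationMap:
    """Direct and DAG-propagated term -> gene-set annotations."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.direct.values():
            out |= gs
        return out


@dataclass
class EnrichmentProfile:
    """Significant terms of one entity with their Fisher-test counts."""

    entity_id: str
    terms: list[tuple[str, float, int, int, int, int]] = field(default_factory=list)
    table: pd.DataFrame | None = None  # all tested terms, for inspection

    def term_set(self) -> set[str]:
        return {t for t, *_ in self.terms}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.terms, columns=["term", "p", "k", "K", "n", "M"]
        ).assign(entity=self.entity_id)


def build_annotation_map(
    gene_terms: Iterable[tuple[str, str]], dag: OntologyDag
) -> AnnotationMap:
    """Build direct annotations from (gene, term) pairs and propagate them.

    A gene annotated to a term is implicitly annotated to every ancestor
    of that term (true-path rule).  Pairs naming terms outside the DAG
    are dropped with a log message.
    """
    direct: dict[str, set[str]] = {t: set() for t in dag.graph.nodes}
    n_dropped = 0
    for gene, term in gene_terms:
        if term in direct:
            direct[term].add(gene)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("dropped %d annotations to terms outside the DAG", n_dropped)
    propagated: dict[str, set[str]] = {t: set(g) for t, g in direct.items()}
    import networkx as nx

    for term in nx.topological_sort(dag.graph):  # children before parents
        for parent in dag.graph.successors(term):
            propagated[parent] |= propagated[term]
    return AnnotationMap(direct=direct, propagated=propagated)


def fisher_enrich_term(k: int, n: int, K: int, M: int) -> float:
    """One-sided over-representation p-value P(X >= k).

    X ~ Hypergeometric(M, K, n): k study hits among n study genes when K
    of the M background genes carry the annotation.
    """
    if not (0 <= k <= min(n, K) and n <= M and K <= M):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, M={M}")
    return float(hypergeom.sf(k - 1, M, K, n))


def _elim_order(dag: OntologyDag) -> list[str]:
    """Most-specific-first processing order: decreasing depth, then id."""
    depths = dag.depths()
    return sorted(dag.graph.nodes, key=lambda t: (-depths[t], t))


def elim_enrich(
    study_genes: Iterable[str],
    annotation: AnnotationMap,
    dag: OntologyDag,
    alpha: float = 0.01,
    entity_id: str = "",
    background: set[str] | None = None,
) -> EnrichmentProfile:
    """elim enrichment of a study gene set against the annotation map.

    Terms are processed from most specific to least (by decreasing
    longest-path depth).  When a term's p-value falls below ``alpha``,
    its propagated genes are removed from every ancestor's annotation
    set before the ancestors are tested.  The significance threshold
    used for pruning equals the reporting threshold.
    """
    if background is None:
        background = annotation.genes
    study = set(study_genes) & background
    if not study:
        logger.warning("%s: empty study set, empty profile", entity_id)
        return EnrichmentProfile(entity_id=entity_id)
    n = len(study)
    M = len(background)
    removed: dict[str, set[str]] = {}
    rows = []
    significant = []
    for term in _elim_order(dag):
        ann = annotation.propagated.get(term, set()) & background
        ann = ann - removed.get(term, set())
        K = len(ann)
        if K == 0:
            continue
        k = len(study & ann)
        p = fisher_enrich_term(k, n, K, M)
        rows.append((term, p, k, K, n, M))
        if p < alpha:
            significant.append((term, p, k, K, n, M))
            pruned = annotation.propagated.get(term, set())
            for anc in dag.ancestors(term) - {term}:
                removed.setdefault(anc, set()).update(pruned)
    table = pd.DataFrame(rows, columns=["term", "p", "k", "K", "n", "M"])
    significant.sort(key=lambda r: (r[1], r[0]))
    return EnrichmentProfile(entity_id=entity_id, terms=significant, table=table)


def classic_enrich(
    study_genes: Iterable[str],
    annotation: AnnotationMap,
    dag: OntologyDag,
    alpha: float = 0.01,
    entity_id: str = "",
    background: set[str] | None = None,
) -> EnrichmentProfile:
    """Plain Fisher enrichment of every term, no elim pruning."""
    if background is None:
        background = annotation.genes
    study = set(study_genes) & background
    if not study:
        logger.warning("%s: empty study set, empty profile", entity_id)
        return EnrichmentProfile(entity_id=entity_id)
    n = len(study)
    M = len(background)
    rows = []
    significant = []
    for term in sorted(dag.graph.nodes):
        ann = annotation.propagated.get(term, set()) & background
        K = len(ann)
        if K == 0:
            continue
        k = len(study & ann)
        p = fisher_enrich_term(k, n, K, M)
        rows.append((term, p, k, K, n, M))
        if p < alpha:
            significant.append((term, p, k, K, n, M))
    table = pd.DataFrame(rows, columns=["term", "p", "k", "K", "n", "M"])
    significant.sort(key=lambda r: (r[1], r[0]))
    return EnrichmentProfile(entity_id=entity_id, terms=significant, table=table)
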