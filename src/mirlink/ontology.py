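"""Ontology DAG handling and semantic similarity.

The similarity machinery here is structural: a term's information content
(IC) is derived from how many terms sit below it in the is_a hierarchy,
not from annotation frequencies.  With ``n_t`` the number of a term's
descendants plus itself and ``N`` the total number of terms in the
namespace, ``p(t) = n_t / N`` and ``IC(t) = -ln p(t)``, so the root has
IC 0 and leaves carry the most information.

Two terms are compared with the Lin measure,

    sim(t1, t2) = 2 * IC(MICA) / (IC(t1) + IC(t2)),

where the MICA is the most-informative common ancestor (a term counts as
its own ancestor).  Two term *sets* are compared with the best-match
average (BMA): the mean of the per-row and per-column maxima of the
pairwise Lin matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet

__all__ = [
    "OntologyDag",
    "TermIC",
    "TermSetSimilarity",
    "load_obo",
    "information_content",
    "mica",
    "lin_similarity",
    "bma_similarity",
    "LinCache",
]


class OntologyError(ValueError):
    """Raised for malformed ontology input (cycles, missing namespace...)."""


@dataclass(frozen=True)
class TermIC:
    """Structural information content of one term."""

    term: str
    n_t: int
    p_t: float
    ic: float


@dataclass
class TermSetSimilarity:
    """BMA similarity between two term sets plus the underlying Lin matrix."""

    score: float
    pair_matrix: np.ndarray
    rows: tuple[str, ...]
    cols: tuple[str, ...]


@dataclass
class OntologyDag:
    """Directed acyclic graph of ontology terms.

    Edges point child -> parent (is_a only).  Exactly one root exists for
    the retained namespace.
    """

    graph: nx.DiGraph
    namespace: str
    root: str = field(init=False)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            edge = next(iter(nx.find_cycle(self.graph)))
            raise OntologyError(
                f"ontology graph is cyclic (cycle contains edge {edge[0]} -> {edge[1]})"
            )
        roots = [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one root for namespace {self.namespace!r}, "
                f"found {len(roots)}: {sorted(roots)[:5]}"
            )
        object.__setattr__(self, "root", roots[0])

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def descendants(self, term: str) -> set[str]:
        """All terms below ``term`` in the hierarchy (excluding itself)."""
        # edges run child -> parent, so hierarchy descendants are the
        # graph-theoretic ancestors of the node
        return nx.ancestors(self.graph, term)

    def ancestors(self, term: str) -> set[str]:
        """All terms above ``term`` plus the term itself."""
        return nx.descendants(self.graph, term) | {term}

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def depths(self) -> dict[str, int]:
        """Longest-path depth from the root for every term (root = 0)."""
        depth = {self.root: 0}
        # reverse topological order of child->parent graph visits parents first
        for term in reversed(list(nx.topological_sort(self.graph))):
            if term == self.root:
                continue
            depth[term] = 1 + max(depth[p] for p in self.graph.successors(term))
        return depth


def load_obo(path, namespace: str = "biological_process") -> OntologyDag:
    """Read an OBO 1.2 file into an :class:`OntologyDag`.

    Obsolete terms are dropped, only ``is_a`` edges are kept, and the
    graph is restricted to ``namespace``.
    """
    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    graph = nx.DiGraph()
    kept = {
        t
        for t, data in multigraph.nodes(data=True)
        if data.get("namespace", namespace) == namespace
    }
    if not kept:
        raise OntologyError(f"no terms with namespace {namespace!r} in {path}")
    graph.add_nodes_from(kept)
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a" and child in kept and parent in kept:
            graph.add_edge(child, parent)
    return OntologyDag(graph=graph, namespace=namespace)


def information_content(dag: OntologyDag) -> dict[str, TermIC]:
    """Structural IC for every term: ``-ln(n_t / N)`` with descendant counts."""
    n_total = len(dag)
    out: dict[str, TermIC] = {}
    # count descendants bottom-up in one topological pass over child->parent
    # edges; sets are needed (not counts) because of multiple inheritance
    below: dict[str, set[str]] = {t: set() for t in dag.graph.nodes}
    for term in nx.topological_sort(dag.graph):
        for parent in dag.graph.successors(term):
            below[parent] |= below[term]
            below[parent].add(term)
    for term in dag.graph.nodes:
        n_t = len(below[term]) + 1
        p_t = n_t / n_total
        out[term] = TermIC(term=term, n_t=n_t, p_t=p_t, ic=-math.log(p_t))
    return out


def mica(t1: str, t2: str, ic_map: Mapping[str, TermIC], dag: OntologyDag) -> str:
    """Most-informative common ancestor; IC ties broken lexicographically."""
    common = dag.ancestors(t1) & dag.ancestors(t2)
    best_ic = max(ic_map[t].ic for t in common)
    return min(t for t in common if ic_map[t].ic == best_ic)


def lin_similarity(
    t1: str, t2: str, ic_map: Mapping[str, TermIC], dag: OntologyDag
) -> float:
    """Lin similarity ``2*IC(MICA) / (IC(t1) + IC(t2))`` in [0, 1].

    The degenerate root pair (IC sum 0) is defined as 1.0 for identical
    terms and 0.0 otherwise.
    """
    for t in (t1, t2):
        if t not in dag:
            raise KeyError(f"term {t!r} not in ontology")
    denom = ic_map[t1].ic + ic_map[t2].ic
    if denom == 0.0:
        return 1.0 if t1 == t2 else 0.0
    return 2.0 * ic_map[mica(t1, t2, ic_map, dag)].ic / denom


class LinCache:
    """Memoised Lin similarity over one (dag, ic_map) pair.

    BMA over many entity pairs re-evaluates the same term pairs
    constantly; caching makes network construction and the permutation
    null affordable.
    """

    def __init__(self, ic_map: Mapping[str, TermIC], dag: OntologyDag):
        self.ic_map = ic_map
        self.dag = dag
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        value = self._cache.get(key)
        if value is None:
            value = lin_similarity(t1, t2, self.ic_map, self.dag)
            self._cache[key] = value
        return value


def bma_similarity(
    set1: Iterable[str],
    set2: Iterable[str],
    ic_map: Mapping[str, TermIC],
    dag: OntologyDag,
    lin: LinCache | None = None,
) -> TermSetSimilarity:
    """Best-match-average similarity between two term sets.

    Builds the |S1| x |S2| Lin matrix and returns
    ``(sum of row maxima + sum of column maxima) / (|S1| + |S2|)``.
    """
    rows = tuple(sorted(set(set1)))
    cols = tuple(sorted(set(set2)))
    if not rows or not cols:
        raise ValueError("bma_similarity requires two non-empty term sets")
    if lin is None:
        lin = LinCache(ic_map, dag)
    matrix = np.empty((len(rows), len(cols)))
    for i, t1 in enumerate(rows):
        for j, t2 in enumerate(cols):
            matrix[i, j] = lin(t1, t2)
    score = (matrix.max(axis=1).sum() + matrix.max(axis=0).sum()) / (
        len(rows) + len(cols)
    )
    return TermSetSimilarity(score=float(score), pair_matrix=matrix, rows=rows, cols=cols)


def bma_score_from_matrix(matrix: np.ndarray) -> float:
    """BMA combination of an arbitrary pairwise-similarity matrix."""
    matrix = np.asarray(matrix, dtype=float)
    return float(
        (matrix.max(axis=1).sum() + matrix.max(axis=0).sum()) / sum(matrix.shape)
    )


def write_ic_table(ic_map: Mapping[str, TermIC], path) -> None:
    """Write the IC table as TSV with columns term, n_t, p, ic."""
    import pandas as pd

    rows = [(v.term, v.n_t, v.p_t, v.ic) for v in ic_map.values()]
    df = pd.DataFrame(rows, columns=["term", "n_t", "p", "ic"]).sort_values("term")
    df.to_csv(path, sep="\t", index=False)
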