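"""Small molecule x miRNA functional-similarity network.

Every (small molecule, miRNA) pair is scored with the BMA/Lin
similarity of their enriched-term sets.  The pooled scores are
approximately normal; the association threshold is the upper
one-sided quantile of a moment-matched normal fit,

    cutoff = mu + z(1 - alpha) * sigma,

and pairs scoring at or above the cutoff form the bipartite
association network.  Auxiliary scores: Meet/Min overlap of target-gene
sets, Tanimoto similarity of binary fingerprints, consensus voting over
target-prediction tables, and the shared-target vs similarity rank
correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import LinCache, OntologyDag, TermIC, bma_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "NormalFit",
    "AssociationNetwork",
    "build_similarity_matrix",
    "normal_cutoff",
    "fit_threshold",
    "threshold_network",
    "meet_min",
    "tanimoto",
    "vote_targets",
    "overlap_vs_similarity",
]


@dataclass
class SimilarityMatrix:
    """Small-molecule (rows) x miRNA (cols) BMA similarity scores."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("similarity scores must be finite")
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("similarity scores must lie in [0, 1]")

    def flat(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float).ravel()


@dataclass
class NormalFit:
    """Moment-matched normal fit with its upper one-sided cutoff."""

    mu: float
    sigma: float
    alpha: float
    cutoff: float


@dataclass
class AssociationNetwork:
    """Thresholded bipartite edge list with node degrees."""

    edges: pd.DataFrame  # columns: small_molecule, mirna, score
    cutoff: float

    @property
    def sm_degrees(self) -> pd.Series:
        return self.edges["small_molecule"].value_counts()

    @property
    def mirna_degrees(self) -> pd.Series:
        return self.edges["mirna"].value_counts()

    def edge_set(self) -> set[tuple[str, str]]:
        return set(
            zip(self.edges["small_molecule"], self.edges["mirna"])
        )

    def drug_mirnas(self) -> dict[str, set[str]]:
        """miRNA partner set of every small molecule in the network."""
        return {
            sm: set(grp["mirna"])
            for sm, grp in self.edges.groupby("small_molecule")
        }


def build_similarity_matrix(
    sm_profiles: Mapping[str, Iterable[str]],
    mirna_profiles: Mapping[str, Iterable[str]],
    dag: OntologyDag,
    ic_map: Mapping[str, TermIC],
    lin: LinCache | None = None,
) -> SimilarityMatrix:
    """BMA similarity between every small molecule and miRNA term set.

    Profiles map entity id -> set of enriched terms; entities with empty
    term sets are dropped with a log message.
    """
    if lin is None:
        lin = LinCache(ic_map, dag)
    sm_sets = {e: set(ts) for e, ts in sm_profiles.items() if set(ts)}
    mir_sets = {e: set(ts) for e, ts in mirna_profiles.items() if set(ts)}
    for name, full, kept in (
        ("small molecules", sm_profiles, sm_sets),
        ("miRNAs", mirna_profiles, mir_sets),
    ):
        if len(kept) < len(full):
            logger.info("dropped %d %s with empty profiles", len(full) - len(kept), name)
    sm_ids = sorted(sm_sets)
    mir_ids = sorted(mir_sets)
    scores = np.zeros((len(sm_ids), len(mir_ids)))
    for i, sm in enumerate(sm_ids):
        for j, mir in enumerate(mir_ids):
            scores[i, j] = bma_similarity(
                sm_sets[sm], mir_sets[mir], ic_map, dag, lin=lin
            ).score
    matrix = SimilarityMatrix(pd.DataFrame(scores, index=sm_ids, columns=mir_ids))
    if matrix.scores.size and matrix.flat().max() == 0:
        logger.warning("all similarity scores are zero (no shared vocabulary?)")
    return matrix


def normal_cutoff(mu: float, sigma: float, alpha: float) -> float:
    """Upper one-sided normal quantile ``mu + z(1 - alpha) * sigma``."""
    return float(mu + stats.norm.ppf(1.0 - alpha) * sigma)


def fit_threshold(scores: Sequence[float] | np.ndarray, alpha: float = 0.01) -> NormalFit:
    """Moment-match a normal to the scores and derive the cutoff."""
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size < 2:
        raise ValueError("need at least 2 scores to fit")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    mu = float(scores.mean())
    sigma = float(scores.std(ddof=1))
    if sigma == 0:
        raise ValueError("zero variance: cannot fit a threshold")
    return NormalFit(mu=mu, sigma=sigma, alpha=alpha, cutoff=normal_cutoff(mu, sigma, alpha))


def threshold_network(matrix: SimilarityMatrix, fit: NormalFit) -> AssociationNetwork:
    """Keep pairs with score >= cutoff as bipartite association edges."""
    rows = []
    for sm in matrix.scores.index:
        for mir in matrix.scores.columns:
            score = matrix.scores.at[sm, mir]
            if score >= fit.cutoff:
                rows.append((sm, mir, float(score)))
    edges = pd.DataFrame(rows, columns=["small_molecule", "mirna", "score"])
    return AssociationNetwork(edges=edges, cutoff=fit.cutoff)


def meet_min(set1: Iterable[str], set2: Iterable[str]) -> float:
    """Overlap coefficient |A∩B| / min(|A|, |B|)."""
    a, b = set(set1), set(set2)
    if not a or not b:
        raise ValueError("meet_min requires two non-empty sets")
    return len(a & b) / min(len(a), len(b))


def tanimoto(fp1: Sequence[int] | str, fp2: Sequence[int] | str) -> float:
    """Tanimoto coefficient of two equal-length binary fingerprints.

    Accepts 0/1 sequences or bitstrings; two all-zero fingerprints score 0.
    """
    a = np.asarray([int(b) for b in fp1], dtype=bool)
    b = np.asarray([int(b) for b in fp2], dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def vote_targets(
    prediction_tables: Sequence[Mapping[str, Iterable[str]]],
    min_algorithms: int = 2,
) -> dict[str, set[str]]:
    """Consensus miRNA->target map: keep pairs found by >= min_algorithms.

    Each table maps miRNA -> predicted target genes from one algorithm;
    a (miRNA, gene) pair counts once per table it appears in.
    """
    if len(prediction_tables) < 2:
        raise ValueError("need predictions from at least two algorithms")
    counts: dict[tuple[str, str], int] = {}
    for table in prediction_tables:
        for mirna, genes in table.items():
            for gene in set(genes):
                counts[(mirna, gene)] = counts.get((mirna, gene), 0) + 1
    out: dict[str, set[str]] = {}
    for (mirna, gene), n in counts.items():
        if n >= min_algorithms:
            out.setdefault(mirna, set()).add(gene)
    return out


def overlap_vs_similarity(
    network: AssociationNetwork,
    sm_targets: Mapping[str, Iterable[str]],
    mirna_targets: Mapping[str, Iterable[str]],
) -> dict:
    """Spearman correlation between shared-target counts and edge scores.

    For each network edge with target information on both sides, counts
    the genes targeted by both the drug and the miRNA, then rank-
    correlates those counts against the edge similarity scores (ties
    mid-ranked).  Fewer than 3 usable edges, or constant counts, leave
    the correlation undefined.
    """
    shared_counts = []
    scores = []
    per_edge = []
    for _, row in network.edges.iterrows():
        sm, mir, score = row["small_molecule"], row["mirna"], row["score"]
        if sm not in sm_targets or mir not in mirna_targets:
            continue
        k = len(set(sm_targets[sm]) & set(mirna_targets[mir]))
        shared_counts.append(k)
        scores.append(score)
        per_edge.append((sm, mir, k, score))
    report = {
        "edges": pd.DataFrame(
            per_edge, columns=["small_molecule", "mirna", "shared_targets", "score"]
        ),
        "r": None,
        "p": None,
        "defined": False,
    }
    if len(shared_counts) < 3:
        return report
    if len(set(shared_counts)) == 1 or len(set(scores)) == 1:
        return report
    r, p = stats.spearmanr(shared_counts, scores)
    report.update(r=float(r), p=float(p), defined=True)
    return report
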