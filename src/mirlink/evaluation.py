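"""Permutation-null ROC evaluation of predicted associations.

For each gold-standard (small molecule, miRNA) pair, the miRNA's
enriched-term set is replaced by a random term set of the same size and
the BMA similarity to the small molecule is recomputed; repeating this
``n_perm`` times yields the negative score population.  Positives are
the true-pair scores.  AUC is computed as the Mann–Whitney U statistic
over positive-negative comparisons (ties half-credit), which equals the
trapezoidal area under the threshold-sweep ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .ontology import LinCache, OntologyDag, TermIC, bma_similarity

__all__ = ["RocInput", "permuted_scores", "build_roc_input", "roc_auc"]


@dataclass
class RocInput:
    """Scored positive and negative instances for ROC evaluation."""

    positives: list[tuple[str, float]]
    negatives: list[tuple[str, float]]

    def __post_init__(self) -> None:
        for _, s in self.positives + self.negatives:
            if not np.isfinite(s):
                raise ValueError("all scores must be finite")


def permuted_scores(
    sm_terms: Iterable[str],
    mirna_terms: Iterable[str],
    term_universe: Iterable[str],
    dag: OntologyDag,
    ic_map: Mapping[str, TermIC],
    n_perm: int = 99,
    seed: int = 0,
    lin: LinCache | None = None,
) -> list[float]:
    """Null similarity scores for one gold pair.

    Draws ``n_perm`` random term sets of the miRNA's set size (without
    replacement, from ``term_universe``) and scores each against the
    small molecule's true term set.  Deterministic under ``seed``.
    """
    sm_terms = set(sm_terms)
    size = len(set(mirna_terms))
    universe = sorted(set(term_universe))
    if size > len(universe):
        raise ValueError(
            f"term universe ({len(universe)}) smaller than required set size ({size})"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if lin is None:
        lin = LinCache(ic_map, dag)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_perm):
        fake = rng.choice(len(universe), size=size, replace=False)
        fake_terms = {universe[i] for i in fake}
        out.append(bma_similarity(sm_terms, fake_terms, ic_map, dag, lin=lin).score)
    return out


def build_roc_input(
    gold_pairs: Sequence[tuple[str, str]],
    sm_profiles: Mapping[str, Iterable[str]],
    mirna_profiles: Mapping[str, Iterable[str]],
    dag: OntologyDag,
    ic_map: Mapping[str, TermIC],
    term_universe: Iterable[str] | None = None,
    n_perm: int = 99,
    seed: int = 0,
) -> RocInput:
    """Score gold pairs and their permutation nulls.

    By default the random-term pool is the union of all terms enriched
    in any entity; pass ``term_universe`` to override (e.g. the full
    DAG).  Pair ``i`` uses sub-seed ``seed + i`` so the negative sets
    are independent across pairs yet reproducible.
    """
    lin = LinCache(ic_map, dag)
    if term_universe is None:
        pool: set[str] = set()
        for terms in list(sm_profiles.values()) + list(mirna_profiles.values()):
            pool |= set(terms)
    else:
        pool = set(term_universe)
    positives = []
    negatives = []
    for i, (sm, mir) in enumerate(gold_pairs):
        sm_terms = set(sm_profiles[sm])
        mir_terms = set(mirna_profiles[mir])
        true_score = bma_similarity(sm_terms, mir_terms, ic_map, dag, lin=lin).score
        positives.append((f"{sm}|{mir}", true_score))
        fakes = permuted_scores(
            sm_terms, mir_terms, pool, dag, ic_map, n_perm=n_perm,
            seed=seed + i, lin=lin,
        )
        negatives.extend((f"{sm}|{mir}|perm{j}", s) for j, s in enumerate(fakes))
    return RocInput(positives=positives, negatives=negatives)


def roc_auc(roc_input: RocInput) -> tuple[float, pd.DataFrame]:
    """AUC and ROC curve points for scored positives/negatives.

    AUC is the Mann–Whitney U statistic divided by n_pos * n_neg (tied
    scores get half credit); the curve is the standard threshold sweep.
    """
    pos = np.asarray([s for _, s in roc_input.positives], dtype=float)
    neg = np.asarray([s for _, s in roc_input.negatives], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    auc = float(u / (pos.size * neg.size))
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, thresholds = roc_curve(y, np.concatenate([pos, neg]))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return auc, curve
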