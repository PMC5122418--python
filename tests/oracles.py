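"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive (enumeration, exact-fraction
summation, hand tabulation) and shares no code with the implementation
it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_upper_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n) by exact pmf summation."""
    total = Fraction(0)
    denom = comb(M, n)
    for x in range(k, min(n, K) + 1):
        total += Fraction(comb(K, x) * comb(M - K, n - x), denom)
    return float(total)


def brute_force_mica_ic(t1: str, t2: str, parents: dict[str, set[str]],
                        ic: dict[str, float]) -> float:
    """Max IC over all common ancestors, ancestors found by path walking."""

    def all_ancestors(t: str) -> set[str]:
        out = {t}
        frontier = [t]
        while frontier:
            cur = frontier.pop()
            for p in parents.get(cur, set()):
                if p not in out:
                    out.add(p)
                    frontier.append(p)
        return out

    common = all_ancestors(t1) & all_ancestors(t2)
    return max(ic[t] for t in common)


def naive_bma(matrix: np.ndarray) -> float:
    """Double-loop best-match average of a similarity matrix."""
    n_rows, n_cols = matrix.shape
    total = 0.0
    for i in range(n_rows):
        best = -np.inf
        for j in range(n_cols):
            best = max(best, matrix[i, j])
        total += best
    for j in range(n_cols):
        best = -np.inf
        for i in range(n_rows):
            best = max(best, matrix[i, j])
        total += best
    return total / (n_rows + n_cols)


def hand_bh(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, written straight from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(pvals[i] * m / rank_from_top, running_min)
        running_min = value
        adjusted[i] = value
    return adjusted


def mantel_haenszel_logrank(time, event, group) -> float:
    """Two-group log-rank chi-square by explicit event-table tabulation."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    event_times = sorted(set(time[event == 1]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == group[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == group[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def km_product_limit(time, event) -> list[tuple[float, float]]:
    """Kaplan-Meier estimate as explicit (time, survival) products."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    s = 1.0
    out = [(0.0, 1.0)]
    for t in sorted(set(time[event == 1])):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= (n - d) / n
        out.append((float(t), s))
    return out


def auc_by_pair_counting(pos, neg) -> float:
    """AUC as the fraction of (pos, neg) pairs correctly ordered, ties 1/2."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def spearman_by_rank_formula(x, y) -> float:
    """Spearman rho as Pearson correlation of mid-ranks."""

    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return np.asarray(ranks)

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
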