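"""Differential-expression calling for perturbation signatures.

Three callers cover the designs found in perturbation compendia:

* ``call_de_sam`` — SAM-style moderated t-statistic with a
  permutation-estimated FDR, for single-channel designs with replicates
  in both classes.
* ``call_de_foldchange`` — 2-fold-change rule with a strict-majority
  vote across samples, for singleton-class or double-channel (ratio)
  designs.
* ``amplitude`` — the cMap amplitude statistic
  ``A = (t - c) / ((t + c) / 2)``; |A| > 2/3 corresponds to more than a
  2-fold change between treatment and control.

Per-dataset signatures for the same entity are merged with
``combine_signatures`` (direction supported in at least ``min_support``
datasets; genes qualifying in both directions are discarded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfile",
    "SignatureSet",
    "amplitude",
    "amplitude_signature",
    "call_de_sam",
    "call_de_foldchange",
    "combine_signatures",
]

TREATMENT = "treatment"
CONTROL = "control"


@dataclass
class ExpressionProfile:
    """Two-class expression matrix (genes x samples).

    ``channel_mode='double'`` means each column already holds per-sample
    treatment/control ratios (no separate control columns).  ``is_log2``
    marks values on log2 scale; the ratio/amplitude callers unlog first
    since their formulas presume a linear scale.
    """

    matrix: pd.DataFrame
    class_labels: pd.Series | None = None
    channel_mode: Literal["single", "double"] = "single"
    is_log2: bool = False

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            raise ValueError("gene identifiers must be unique")
        if self.channel_mode == "single":
            if self.class_labels is None:
                raise ValueError("single-channel profiles need class labels")
            self.class_labels = self.class_labels.reindex(self.matrix.columns)
            counts = self.class_labels.value_counts()
            for cls in (TREATMENT, CONTROL):
                if counts.get(cls, 0) < 1:
                    raise ValueError(f"need at least one {cls} sample")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def linear_values(self) -> pd.DataFrame:
        return np.exp2(self.matrix) if self.is_log2 else self.matrix

    def split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        labels = self.class_labels
        return (
            self.matrix.loc[:, labels[labels == TREATMENT].index],
            self.matrix.loc[:, labels[labels == CONTROL].index],
        )


@dataclass
class SignatureSet:
    """Up/down differentially-expressed gene sets of one entity."""

    entity_id: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        conflict = self.up & self.down
        if conflict:
            logger.info("%s: discarding %d conflict genes", self.entity_id, len(conflict))
            self.up -= conflict
            self.down -= conflict

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def genes(self) -> set[str]:
        return self.up | self.down


def amplitude(t: float, c: float) -> float:
    """cMap amplitude ``(t - c) / ((t + c) / 2)``, bounded in (-2, 2).

    Requires non-negative treatment and control values, not both zero
    (callers skip such probes).
    """
    if t < 0 or c < 0:
        raise ValueError("amplitude requires non-negative expression values")
    if t == 0 and c == 0:
        raise ValueError("amplitude undefined for t=c=0")
    return (t - c) / (0.5 * (t + c))


def amplitude_signature(
    profile: ExpressionProfile, entity_id: str = "", cutoff: float = 2.0 / 3.0
) -> SignatureSet:
    """Call DE genes by the amplitude rule: A > cutoff up, A < -cutoff down.

    ``t`` is the mean of treatment columns and ``c`` the mean of matched
    control columns, on linear scale.  Probes with t=c=0 are skipped and
    counted in the log.
    """
    values = ExpressionProfile(
        profile.linear_values(), profile.class_labels, profile.channel_mode
    )
    t_mat, c_mat = values.split()
    t = t_mat.mean(axis=1)
    c = c_mat.mean(axis=1)
    undefined = (t == 0) & (c == 0)
    if undefined.any():
        logger.info("%s: %d probes with t=c=0 skipped", entity_id, int(undefined.sum()))
    valid = ~undefined
    a = pd.Series(np.nan, index=profile.genes)
    tv, cv = t[valid], c[valid]
    a[valid] = (tv - cv) / (0.5 * (tv + cv))
    return SignatureSet(
        entity_id=entity_id,
        up=set(a.index[a > cutoff]),
        down=set(a.index[a < -cutoff]),
    )


def _sam_d_statistic(
    x: np.ndarray, treat_mask: np.ndarray, s0: float | None = None
) -> tuple[np.ndarray, float]:
    """Unpaired two-class SAM d-statistic with fudge factor s0.

    s0 defaults to the median of the gene-wise pooled standard errors.
    """
    xt = x[:, treat_mask]
    xc = x[:, ~treat_mask]
    nt, nc = xt.shape[1], xc.shape[1]
    mt = xt.mean(axis=1)
    mc = xc.mean(axis=1)
    ss = ((xt - mt[:, None]) ** 2).sum(axis=1) + ((xc - mc[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / nt + 1.0 / nc) * ss / (nt + nc - 2))
    if s0 is None:
        s0 = float(np.median(s))
    num = mt - mc
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(num == 0, 0.0, num / denom)
    return d, s0


def call_de_sam(
    profile: ExpressionProfile,
    fdr_cutoff: float = 0.05,
    entity_id: str = "",
    n_perm: int = 100,
    seed: int = 0,
) -> SignatureSet:
    """SAM-style DE caller with permutation-estimated FDR.

    Genes are ranked by |d|; for each candidate threshold the FDR is the
    mean number of permuted |d| values exceeding it divided by the
    observed count, made monotone by a step-up pass.  The largest gene
    list with estimated FDR <= ``fdr_cutoff`` is returned, split by the
    sign of the mean difference.
    """
    if profile.channel_mode != "single":
        raise ValueError("SAM caller requires a single-channel profile")
    treat_mask = (profile.class_labels == TREATMENT).to_numpy()
    if treat_mask.sum() < 2 or (~treat_mask).sum() < 2:
        raise ValueError("SAM caller requires >=2 samples per class")
    x = profile.matrix.to_numpy(dtype=float)
    d_obs, s0 = _sam_d_statistic(x, treat_mask)
    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]

    rng = np.random.default_rng(seed)
    n_samples = x.shape[1]
    exceed = np.zeros((n_perm, len(thresholds)))
    pooled_perm = np.empty((n_perm, len(d_obs)))
    for b in range(n_perm):
        perm = rng.permutation(n_samples)
        d_perm, _ = _sam_d_statistic(x[:, perm], treat_mask, s0=s0)
        pooled_perm[b] = d_perm
        abs_perm = np.sort(np.abs(d_perm))
        # count permuted |d| >= each observed threshold
        exceed[b] = len(abs_perm) - np.searchsorted(abs_perm, thresholds, side="left")
    # pi0: share of genes behaving null, from the fraction of observed d
    # inside the interquartile range of the permuted d; the false-call
    # count is the permutation median — both SAM conventions
    q25, q75 = np.percentile(pooled_perm, [25, 75])
    pi0 = min(1.0, ((d_obs >= q25) & (d_obs <= q75)).sum() / (0.5 * len(d_obs)))
    expected_false = pi0 * np.median(exceed, axis=0)
    k = np.arange(1, len(thresholds) + 1)
    with np.errstate(divide="ignore"):
        fdr = np.minimum(expected_false / k, 1.0)
    # null genes with |d| = 0 can never be called
    fdr[thresholds == 0] = 1.0
    # step-up: take the most generous threshold at or below each rank
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    passing = np.nonzero(fdr <= fdr_cutoff)[0]
    if fdr_cutoff <= 0 or len(passing) == 0:
        return SignatureSet(entity_id=entity_id)
    selected = order[: passing[-1] + 1]
    genes = profile.genes
    up = {genes[i] for i in selected if d_obs[i] > 0}
    down = {genes[i] for i in selected if d_obs[i] < 0}
    return SignatureSet(entity_id=entity_id, up=up, down=down)


def call_de_foldchange(
    profile: ExpressionProfile, entity_id: str = "", fold: float = 2.0
) -> SignatureSet:
    """2-fold-change caller with a strict-majority vote across samples.

    Single-channel: each treatment sample's value is divided by the mean
    of the control columns.  Double-channel: each column is already a
    per-sample ratio.  A gene is up in a sample if ratio >= ``fold`` and
    down if ratio <= 1/``fold``; it is called only when one direction
    holds in strictly more than half of the samples where the ratio was
    computable.
    """
    values = profile.linear_values()
    if profile.channel_mode == "double":
        ratios = values
    else:
        t_mat, c_mat = ExpressionProfile(
            values, profile.class_labels, "single"
        ).split()
        c_mean = c_mat.mean(axis=1)
        ratios = t_mat.div(c_mean, axis=0)
        ratios[c_mean <= 0] = np.nan
    ratios = ratios.where(np.isfinite(ratios))
    n_valid = ratios.notna().sum(axis=1)
    n_up = (ratios >= fold).sum(axis=1)
    n_down = (ratios <= 1.0 / fold).sum(axis=1)
    up = set(ratios.index[(n_valid > 0) & (n_up * 2 > n_valid)])
    down = set(ratios.index[(n_valid > 0) & (n_down * 2 > n_valid)])
    return SignatureSet(entity_id=entity_id, up=up, down=down)


def combine_signatures(
    signatures: Sequence[SignatureSet],
    min_support: int = 2,
    entity_id: str | None = None,
) -> SignatureSet:
    """Merge per-dataset signatures of one entity.

    A gene keeps a direction iff it was called in that direction in at
    least ``min_support`` input signatures; genes qualifying in both
    directions are discarded.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    if entity_id is None:
        entity_id = signatures[0].entity_id
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for sig in signatures:
        for g in sig.up:
            up_counts[g] = up_counts.get(g, 0) + 1
        for g in sig.down:
            down_counts[g] = down_counts.get(g, 0) + 1
    up = {g for g, n in up_counts.items() if n >= min_support}
    down = {g for g, n in down_counts.items() if n >= min_support}
    return SignatureSet(entity_id=entity_id, up=up, down=down)
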