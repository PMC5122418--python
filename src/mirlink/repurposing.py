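"""Drug repositioning by hypergeometric enrichment of shared miRNAs.

A drug's predicted miRNA partners and a disease's curated miRNAs are
compared against a common miRNA universe: with k shared miRNAs out of a
drug set of size n and a disease set of size K in a universe of M, the
pair is scored with the hypergeometric upper tail P(X >= k).  The
Benjamini–Hochberg procedure controls the FDR across all tested pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["DiseaseMiRNAMap", "RepurposingResult", "drug_disease_test", "bh_fdr", "run_repurposing"]


@dataclass
class DiseaseMiRNAMap:
    """Disease -> associated miRNA sets over a declared universe."""

    associations: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        mapped: set[str] = set()
        for mirnas in self.associations.values():
            mapped |= mirnas
        if not self.universe:
            self.universe = set(mapped)
        elif not mapped <= self.universe:
            raise ValueError("mapped miRNAs outside the declared universe")


@dataclass
class RepurposingResult:
    """Drug-disease hypergeometric tests with BH-adjusted significance."""

    table: pd.DataFrame  # drug, disease, shared_mirnas, k, p, fdr (sorted by p)
    fdr_cutoff: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["fdr"] < self.fdr_cutoff]


def drug_disease_test(
    drug_mirnas: Iterable[str],
    disease_mirnas: Iterable[str],
    universe_size: int,
) -> tuple[int, float]:
    """Shared-miRNA count and hypergeometric upper-tail p-value."""
    drug = set(drug_mirnas)
    disease = set(disease_mirnas)
    if len(drug) > universe_size or len(disease) > universe_size:
        raise ValueError("set larger than the declared universe")
    k = len(drug & disease)
    p = float(hypergeom.sf(k - 1, universe_size, len(disease), len(drug)))
    return k, min(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_repurposing(
    drug_mirnas: Mapping[str, Iterable[str]],
    disease_map: DiseaseMiRNAMap,
    fdr_cutoff: float = 0.1,
    universe: set[str] | None = None,
    include_zero_overlap: bool = False,
) -> RepurposingResult:
    """Test every drug x disease pair for miRNA-overlap enrichment.

    The universe defaults to the union of network miRNAs and disease-map
    miRNAs.  Pairs sharing no miRNA are excluded from testing (and from
    the BH family) unless ``include_zero_overlap`` is set, since they
    are non-candidates by construction.
    """
    drug_sets = {d: set(m) for d, m in drug_mirnas.items()}
    if universe is None:
        universe = set().union(*drug_sets.values(), disease_map.universe) if drug_sets else set(disease_map.universe)
    m_size = len(universe)
    for name, sets in (("drug", drug_sets), ("disease", disease_map.associations)):
        for entity, mirnas in sets.items():
            if not mirnas <= universe:
                raise ValueError(f"{name} {entity!r} has miRNAs outside the universe")
    rows = []
    for drug, dm in sorted(drug_sets.items()):
        for disease, zm in sorted(disease_map.associations.items()):
            shared = dm & zm
            if not shared and not include_zero_overlap:
                continue
            k, p = drug_disease_test(dm, zm, m_size)
            rows.append((drug, disease, ",".join(sorted(shared)), k, p))
    table = pd.DataFrame(rows, columns=["drug", "disease", "shared_mirnas", "k", "p"])
    if len(table):
        table["fdr"] = bh_fdr(table["p"])
        table = table.sort_values(["p", "drug", "disease"]).reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
    return RepurposingResult(table=table, fdr_cutoff=fdr_cutoff)
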