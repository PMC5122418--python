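"""Readers and writers for the plain-text formats the pipeline uses.

Expression: TSV with gene ids in the first column and samples across,
plus a sample sheet (sample, class, dataset_id).  Annotations: GMT or
two-column gene/term TSV.  Networks: TSV edge list and GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .diffexpr import ExpressionProfile, SignatureSet
from .enrichment import EnrichmentProfile
from .network import AssociationNetwork
from .repurposing import DiseaseMiRNAMap
from .survival import SurvivalCohort

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "read_gene_term_tsv",
    "write_signatures",
    "write_enrichment",
    "read_fingerprints",
    "read_disease_map",
    "write_network",
    "read_cohort",
    "write_json",
]


def read_expression(
    matrix_path, sample_sheet_path=None, channel_mode: str = "single", is_log2: bool = False
) -> ExpressionProfile:
    """Load an expression TSV plus (for single-channel) its sample sheet."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    labels = None
    if sample_sheet_path is not None:
        sheet = pd.read_csv(sample_sheet_path, sep="\t")
        labels = sheet.set_index("sample")["class"]
    return ExpressionProfile(
        matrix=matrix, class_labels=labels, channel_mode=channel_mode, is_log2=is_log2
    )


def write_expression(profile: ExpressionProfile, matrix_path, sample_sheet_path=None,
                     dataset_id: str = "d1") -> None:
    profile.matrix.to_csv(matrix_path, sep="\t")
    if sample_sheet_path is not None and profile.class_labels is not None:
        pd.DataFrame(
            {
                "sample": profile.class_labels.index,
                "class": profile.class_labels.values,
                "dataset_id": dataset_id,
            }
        ).to_csv(sample_sheet_path, sep="\t", index=False)


def read_gmt(path) -> list[tuple[str, str]]:
    """GMT rows (term, description, gene...) -> (gene, term) pairs."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        term, genes = fields[0], fields[2:]
        pairs += [(g, term) for g in genes if g]
    return pairs


def read_gene_term_tsv(path) -> list[tuple[str, str]]:
    """Two-column TSV (gene, term) -> (gene, term) pairs; header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0].lower() == "gene":
        df = df.iloc[1:]
    return list(df.itertuples(index=False, name=None))


def write_signatures(signatures: list[SignatureSet], path) -> None:
    rows = []
    for sig in signatures:
        rows += [(sig.entity_id, g, "up") for g in sorted(sig.up)]
        rows += [(sig.entity_id, g, "down") for g in sorted(sig.down)]
    pd.DataFrame(rows, columns=["entity", "gene", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def read_signatures(path) -> dict[str, SignatureSet]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, SignatureSet] = {}
    for entity, grp in df.groupby("entity"):
        out[entity] = SignatureSet(
            entity_id=str(entity),
            up=set(grp.loc[grp["direction"] == "up", "gene"]),
            down=set(grp.loc[grp["direction"] == "down", "gene"]),
        )
    return out


def write_enrichment(profiles: list[EnrichmentProfile], path) -> None:
    frames = [p.to_frame() for p in profiles if p.terms]
    columns = ["entity", "term", "p", "k", "n", "K", "M"]
    if frames:
        df = pd.concat(frames)[columns]
    else:
        df = pd.DataFrame(columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_fingerprints(path) -> dict[str, str]:
    """TSV of id + 0/1 bitstring -> id -> bitstring."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return dict(zip(df[0], df[1]))


def read_disease_map(path, universe: set[str] | None = None) -> DiseaseMiRNAMap:
    """TSV (disease_id, mirna) -> DiseaseMiRNAMap."""
    df = pd.read_csv(path, sep="\t", header=None, names=["disease", "mirna"], dtype=str)
    if df.iloc[0, 0].lower() in {"disease", "disease_id"}:
        df = df.iloc[1:]
    assoc: dict[str, set[str]] = {}
    for disease, grp in df.groupby("disease"):
        assoc[str(disease)] = set(grp["mirna"])
    return DiseaseMiRNAMap(associations=assoc, universe=universe or set())


def write_network(network: AssociationNetwork, tsv_path, graphml_path=None) -> None:
    network.edges.to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        g = nx.Graph()
        for _, row in network.edges.iterrows():
            g.add_node(row["small_molecule"], kind="small_molecule")
            g.add_node(row["mirna"], kind="mirna")
            g.add_edge(row["small_molecule"], row["mirna"], score=float(row["score"]))
        nx.write_graphml(g, graphml_path)


def read_cohort(clinical_path, expression_path) -> SurvivalCohort:
    """Clinical TSV (patient, time, event) + patients x miRNAs expression TSV."""
    clin = pd.read_csv(clinical_path, sep="\t").set_index("patient")
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    return SurvivalCohort(
        time=clin["time"], event=clin["event"].astype(int), mirna_expr=expr
    )


def write_cohort(cohort: SurvivalCohort, clinical_path, expression_path) -> None:
    pd.DataFrame(
        {"patient": cohort.patients, "time": cohort.time.values, "event": cohort.event.values}
    ).to_csv(clinical_path, sep="\t", index=False)
    cohort.mirna_expr.to_csv(expression_path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
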