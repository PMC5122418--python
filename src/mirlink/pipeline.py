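"""End-to-end orchestration: DE calling -> enrichment -> similarity ->
threshold -> network, with optional evaluation, repurposing and
survival stages.

``run_pipeline`` reads everything from files referenced by a
:class:`PipelineConfig`, writes each stage's output into a run
directory, and records the configuration and seed alongside the
results so a run is reproducible from its own provenance log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diffexpr import SignatureSet, call_de_foldchange, call_de_sam, combine_signatures
from .enrichment import build_annotation_map, elim_enrich
from .evaluation import build_roc_input, roc_auc
from .io import (
    read_cohort,
    read_disease_map,
    read_expression,
    read_gene_term_tsv,
    read_gmt,
    write_enrichment,
    write_json,
    write_network,
    write_signatures,
)
from .network import build_similarity_matrix, fit_threshold, threshold_network
from .ontology import information_content, load_obo
from .repurposing import run_repurposing
from .survival import stratify

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    ``expression_manifest`` is a TSV with columns entity, kind
    (small_molecule|mirna), dataset_id, matrix, sample_sheet; paths are
    resolved relative to the manifest's directory.
    """

    obo: str = ""
    annotations: str = ""  # GMT (.gmt) or gene/term TSV
    expression_manifest: str = ""
    out_dir: str = "run"
    gold_pairs: str | None = None  # TSV small_molecule, mirna
    disease_map: str | None = None  # TSV disease, mirna
    clinical: str | None = None
    cohort_expression: str | None = None
    alpha_enrich: float = 0.01
    alpha_network: float = 0.01
    fdr_de: float = 0.05
    fold_change: float = 2.0
    amplitude_cutoff: float = 2.0 / 3.0
    min_support: int = 2
    n_perm: int = 99
    fdr_repurpose: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("obo", "annotations", "expression_manifest"):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise PipelineError(f"config: missing required input {name!r}: {path}")
        for name in ("gold_pairs", "disease_map", "clinical", "cohort_expression"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise PipelineError(f"config: input {name!r} does not exist: {path}")
        if not (0 < self.alpha_enrich < 1 and 0 < self.alpha_network < 0.5):
            raise PipelineError("config: alpha thresholds out of range")
        if not (0 <= self.fdr_de <= 1 and 0 < self.fdr_repurpose < 1):
            raise PipelineError("config: FDR thresholds out of range")


def _call_entity_signature(config, entity, rows, manifest_dir) -> SignatureSet:
    per_dataset = []
    for _, row in rows.iterrows():
        profile = read_expression(
            manifest_dir / row["matrix"],
            manifest_dir / row["sample_sheet"] if isinstance(row.get("sample_sheet"), str) else None,
            channel_mode=row.get("channel_mode", "single"),
            is_log2=bool(row.get("is_log2", True)),
        )
        labels = profile.class_labels
        if (
            profile.channel_mode == "single"
            and (labels == "treatment").sum() >= 2
            and (labels == "control").sum() >= 2
        ):
            sig = call_de_sam(profile, fdr_cutoff=config.fdr_de, entity_id=entity,
                              seed=config.seed)
        else:
            sig = call_de_foldchange(profile, entity_id=entity, fold=config.fold_change)
        per_dataset.append(sig)
    if len(per_dataset) == 1:
        return per_dataset[0]
    return combine_signatures(per_dataset, min_support=config.min_support)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    dag = stage("ontology", lambda: load_obo(config.obo))
    ic_map = stage("ontology", lambda: information_content(dag))

    pairs = (
        read_gmt(config.annotations)
        if str(config.annotations).endswith(".gmt")
        else read_gene_term_tsv(config.annotations)
    )
    annotation = stage("annotation", lambda: build_annotation_map(pairs, dag))

    manifest = pd.read_csv(config.expression_manifest, sep="\t")
    manifest_dir = Path(config.expression_manifest).parent

    def de_stage():
        signatures = {}
        for (entity, kind), rows in manifest.groupby(["entity", "kind"]):
            signatures[(entity, kind)] = _call_entity_signature(
                config, entity, rows, manifest_dir
            )
        return signatures

    signatures = stage("de-call", de_stage)
    write_signatures([s for s in signatures.values()], out / "signatures.tsv")

    def enrich_stage():
        profiles = {}
        for (entity, kind), sig in sorted(signatures.items()):
            profiles[(entity, kind)] = elim_enrich(
                sig.genes(), annotation, dag, alpha=config.alpha_enrich, entity_id=entity
            )
        return profiles

    profiles = stage("enrich", enrich_stage)
    write_enrichment(list(profiles.values()), out / "enrichment.tsv")

    sm_profiles = {e: p.term_set() for (e, kind), p in profiles.items() if kind == "small_molecule"}
    mir_profiles = {e: p.term_set() for (e, kind), p in profiles.items() if kind == "mirna"}

    matrix = stage(
        "similarity",
        lambda: build_similarity_matrix(sm_profiles, mir_profiles, dag, ic_map),
    )
    matrix.scores.to_csv(out / "similarity.tsv", sep="\t")
    fit = stage("threshold", lambda: fit_threshold(matrix.flat(), alpha=config.alpha_network))
    network = stage("network", lambda: threshold_network(matrix, fit))
    write_network(network, out / "network.tsv", out / "network.graphml")

    summary: dict = {
        "n_entities": len(signatures),
        "n_small_molecules": len(sm_profiles),
        "n_mirnas": len(mir_profiles),
        "normal_fit": {"mu": fit.mu, "sigma": fit.sigma, "alpha": fit.alpha, "cutoff": fit.cutoff},
        "n_edges": int(len(network.edges)),
    }

    if config.gold_pairs:
        def evaluate():
            gold = pd.read_csv(config.gold_pairs, sep="\t")
            pairs = [
                (r["small_molecule"], r["mirna"])
                for _, r in gold.iterrows()
                if r["small_molecule"] in sm_profiles and r["mirna"] in mir_profiles
            ]
            roc = build_roc_input(
                pairs, sm_profiles, mir_profiles, dag, ic_map,
                n_perm=config.n_perm, seed=config.seed,
            )
            auc, curve = roc_auc(roc)
            curve.to_csv(out / "roc_curve.tsv", sep="\t", index=False)
            return auc, len(roc.positives), len(roc.negatives)

        auc, n_pos, n_neg = stage("evaluate", evaluate)
        summary["evaluation"] = {"auc": auc, "n_positives": n_pos, "n_negatives": n_neg}

    if config.disease_map:
        def repurpose():
            dmap = read_disease_map(config.disease_map)
            result = run_repurposing(
                network.drug_mirnas(), dmap, fdr_cutoff=config.fdr_repurpose
            )
            result.table.to_csv(out / "repurposing.tsv", sep="\t", index=False)
            return int(len(result.significant()))

        summary["repurposing_significant_pairs"] = stage("repurpose", repurpose)

    if config.clinical and config.cohort_expression:
        def survival_stage():
            cohort = read_cohort(config.clinical, config.cohort_expression)
            result = stratify(cohort, seed=config.seed)
            for name, curve in result.km_curves.items():
                curve.to_csv(out / f"km_{name}.tsv", sep="\t", index=False)
            result.labels.rename("group").to_frame().to_csv(out / "groups.tsv", sep="\t")
            return {"logrank_statistic": result.statistic, "logrank_p": result.p_value}

        summary["survival"] = stage("survival", survival_stage)

    config_dict = asdict(config)
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    write_json(
        {"mirlink_version": __version__, "config": config_dict,
         "config_sha256_16": config_hash, "summary": summary},
        out / "provenance.json",
    )
    write_json(summary, out / "summary.json")
    return out
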