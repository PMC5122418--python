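"""Synthetic fixtures with known ground truth for every pipeline stage.

Every generator is a pure function of its parameters and a seed, so
regeneration is bit-identical and each planted signal (DE genes,
associated pairs, enriched drug-disease overlaps, hazard differences)
can be checked against what the pipeline recovers.

Defaults emulate the study conditions of the real analyses at desk
scale: a few-hundred-term ontology, ~10 enriched terms per perturbed
entity, 5-vs-5 or singleton two-class microarray designs, 99-permutation
evaluation nulls, and cohorts of a few hundred patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import CONTROL, TREATMENT, ExpressionProfile
from .ontology import OntologyDag, TermIC, information_content
from .survival import SurvivalCohort

__all__ = [
    "make_dag",
    "dag_to_obo",
    "make_expression",
    "make_association_scenario",
    "make_survival",
    "make_pipeline_scenario",
    "AssociationScenario",
    "PipelineScenario",
]


def _term_id(i: int) -> str:
    return f"T:{i:07d}"


def make_dag(n_terms: int, branching: int = 2, seed: int = 0) -> OntologyDag:
    """Random single-root is_a DAG with ``n_terms`` terms.

    Terms are added sequentially; each picks a primary parent uniformly
    among existing terms with fewer than ``branching`` children (falling
    back to any existing term), plus occasionally a second parent so the
    graph is a true DAG rather than a tree.  Edges always point from a
    later term to an earlier one, guaranteeing acyclicity.
    """
    if n_terms < 3:
        raise ValueError("need at least 3 terms")
    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    graph.add_node(_term_id(0))
    child_count = {0: 0}
    for i in range(1, n_terms):
        open_parents = [j for j, c in child_count.items() if c < branching]
        pool = open_parents if open_parents else list(range(i))
        parent = int(pool[rng.integers(len(pool))])
        graph.add_edge(_term_id(i), _term_id(parent))
        child_count[parent] = child_count.get(parent, 0) + 1
        child_count[i] = 0
        if i > 2 and rng.random() < 0.1:
            second = int(rng.integers(i))
            if second != parent:
                graph.add_edge(_term_id(i), _term_id(second))
    return OntologyDag(graph=graph, namespace="biological_process")


def dag_to_obo(dag: OntologyDag) -> str:
    """Serialise a DAG as OBO 1.2 text (id, name, namespace, is_a)."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in sorted(dag.graph.nodes):
        lines += [
            "[Term]",
            f"id: {term}",
            f"name: synthetic term {term}",
            f"namespace: {dag.namespace}",
        ]
        for parent in sorted(dag.graph.successors(term)):
            lines.append(f"is_a: {parent} ! synthetic term {parent}")
        lines.append("")
    return "\n".join(lines)


def make_expression(
    n_genes: int = 220,
    n_treat: int = 5,
    n_ctrl: int = 5,
    planted_up: int | list[str] = 20,
    planted_down: int | list[str] = 0,
    effect: float = 3.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    scale: str = "log2",
) -> tuple[ExpressionProfile, dict]:
    """Two-class expression matrix with planted up/down genes.

    Baselines are uniform on log2 [5, 10] with Gaussian noise of
    ``noise_sd``; planted genes are shifted by ``effect * noise_sd``
    log2 units in the treatment class.  ``scale`` selects log2 or
    linear output values (ratio-based callers want linear).
    Returns the profile and the planted truth.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    if isinstance(planted_up, int):
        planted_up = genes[:planted_up]
    if isinstance(planted_down, int):
        start = len(planted_up)
        planted_down = genes[start : start + planted_down]
    if set(planted_up) & set(planted_down):
        raise ValueError("planted up/down sets must be disjoint")
    n_samples = n_treat + n_ctrl
    baseline = rng.uniform(5.0, 10.0, size=n_genes)
    log2x = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    shift = effect * noise_sd
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in planted_up:
        log2x[gene_pos[g], :n_treat] += shift
    for g in planted_down:
        log2x[gene_pos[g], :n_treat] -= shift
    columns = [f"t{i}" for i in range(n_treat)] + [f"c{i}" for i in range(n_ctrl)]
    labels = pd.Series([TREATMENT] * n_treat + [CONTROL] * n_ctrl, index=columns)
    matrix = pd.DataFrame(log2x, index=genes, columns=columns)
    is_log2 = scale == "log2"
    if not is_log2:
        matrix = np.exp2(matrix)
    profile = ExpressionProfile(matrix=matrix, class_labels=labels, is_log2=is_log2)
    truth = {
        "planted_up": list(planted_up),
        "planted_down": list(planted_down),
        "effect": effect,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return profile, truth


@dataclass
class AssociationScenario:
    """Term-level profiles with planted small molecule-miRNA pairs."""

    dag: OntologyDag
    ic_map: dict[str, TermIC]
    sm_profiles: dict[str, set[str]]
    mirna_profiles: dict[str, set[str]]
    planted_pairs: list[tuple[str, str]]
    params: dict = field(default_factory=dict)


def make_association_scenario(
    n_sm: int = 20,
    n_mirna: int = 10,
    n_planted_pairs: int = 5,
    term_overlap: float = 0.8,
    n_terms: int = 300,
    terms_per_entity: int = 12,
    branching: int = 2,
    seed: int = 0,
) -> AssociationScenario:
    """Enriched-term profiles with planted associated pairs.

    Background entities draw their term sets independently from the
    non-root terms of a random DAG; each planted pair's small molecule
    shares a ``term_overlap`` fraction of its miRNA's terms, with the
    remainder drawn independently.
    """
    if not 0 < term_overlap <= 1:
        raise ValueError("term_overlap must be in (0, 1]")
    if n_planted_pairs > min(n_sm, n_mirna):
        raise ValueError("more planted pairs than available distinct entities")
    rng = np.random.default_rng(seed)
    dag = make_dag(n_terms, branching=branching, seed=seed)
    ic_map = information_content(dag)
    pool = sorted(dag.terms - {dag.root})

    def sample_terms(exclude: set[str] = frozenset(), size: int = terms_per_entity) -> set[str]:
        avail = [t for t in pool if t not in exclude]
        idx = rng.choice(len(avail), size=size, replace=False)
        return {avail[i] for i in idx}

    sm_ids = [f"SM{i:03d}" for i in range(n_sm)]
    mir_ids = [f"miR-{i:03d}" for i in range(n_mirna)]
    mirna_profiles = {m: sample_terms() for m in mir_ids}
    sm_profiles: dict[str, set[str]] = {}
    planted_pairs = list(zip(sm_ids[:n_planted_pairs], mir_ids[:n_planted_pairs]))
    n_shared = int(round(term_overlap * terms_per_entity))
    for sm, mir in planted_pairs:
        mir_terms = sorted(mirna_profiles[mir])
        shared_idx = rng.choice(len(mir_terms), size=n_shared, replace=False)
        shared = {mir_terms[i] for i in shared_idx}
        extra = sample_terms(exclude=shared, size=terms_per_entity - n_shared)
        sm_profiles[sm] = shared | extra
    for sm in sm_ids[n_planted_pairs:]:
        sm_profiles[sm] = sample_terms()
    return AssociationScenario(
        dag=dag,
        ic_map=ic_map,
        sm_profiles=sm_profiles,
        mirna_profiles=mirna_profiles,
        planted_pairs=planted_pairs,
        params={
            "n_sm": n_sm,
            "n_mirna": n_mirna,
            "n_planted_pairs": n_planted_pairs,
            "term_overlap": term_overlap,
            "n_terms": n_terms,
            "terms_per_entity": terms_per_entity,
            "seed": seed,
        },
    )


def make_survival(
    n_per_group: int = 200,
    hazard_ratio: float = 2.0,
    censor_rate: float = 0.3,
    expr_separation: float = 2.0,
    n_mirnas: int = 2,
    baseline_hazard: float = 0.1,
    seed: int = 0,
) -> tuple[SurvivalCohort, dict]:
    """Two-group cohort with a planted hazard difference.

    Event times are exponential with rate ``baseline_hazard`` in the
    good-prognosis group and ``baseline_hazard * hazard_ratio`` in the
    poor one; censoring times are exponential with a rate chosen so
    roughly ``censor_rate`` of good-group observations are censored.
    miRNA expression is Gaussian, shifted by ``expr_separation`` between
    groups, so clustering can recover the labels.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    group = np.repeat([0, 1], n_per_group)  # 0 = good (baseline hazard)
    rates = np.where(group == 0, baseline_hazard, baseline_hazard * hazard_ratio)
    event_times = rng.exponential(1.0 / rates)
    censor_lambda = baseline_hazard * censor_rate / max(1.0 - censor_rate, 1e-9)
    censor_times = (
        rng.exponential(1.0 / censor_lambda, size=n)
        if censor_lambda > 0
        else np.full(n, np.inf)
    )
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    patients = pd.Index([f"P{i:04d}" for i in range(n)])
    expr = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n, n_mirnas))
        + np.where(group == 0, expr_separation, 0.0)[:, None]
        + 5.0,
        index=patients,
        columns=[f"miR-{i:03d}" for i in range(n_mirnas)],
    )
    cohort = SurvivalCohort(
        time=pd.Series(time, index=patients, name="time"),
        event=pd.Series(event, index=patients, name="event"),
        mirna_expr=expr,
    )
    truth = {
        "group": pd.Series(group, index=patients, name="group"),
        "hazard_ratio": hazard_ratio,
        "censor_rate": censor_rate,
        "expr_separation": expr_separation,
        "seed": seed,
    }
    return cohort, truth


@dataclass
class PipelineScenario:
    """Gene-level scenario for the full file-driven pipeline.

    Entities get planted DE genes drawn from the genes annotated to
    their (planted) enriched terms, measured in two replicate datasets
    so cross-dataset combination is exercised.
    """

    dag: OntologyDag
    annotations: list[tuple[str, str]]  # (gene, term) pairs
    sm_expression: dict[str, list[ExpressionProfile]]
    mirna_expression: dict[str, list[ExpressionProfile]]
    truth: dict


def make_pipeline_scenario(
    n_sm: int = 8,
    n_mirna: int = 5,
    n_planted_pairs: int = 3,
    term_overlap: float = 0.8,
    n_terms: int = 60,
    terms_per_entity: int = 5,
    genes_per_term: int = 8,
    n_null_genes: int = 120,
    n_datasets: int = 2,
    effect: float = 4.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> PipelineScenario:
    """End-to-end scenario starting from raw expression matrices.

    Each leaf-ish term owns ``genes_per_term`` private genes; an
    entity's planted DE genes are the genes of its planted term set, so
    DE calling followed by enrichment should recover approximately that
    set.  Expression for each entity is generated in ``n_datasets``
    replicate 5-vs-5 designs.
    """
    scenario = make_association_scenario(
        n_sm=n_sm,
        n_mirna=n_mirna,
        n_planted_pairs=n_planted_pairs,
        term_overlap=term_overlap,
        n_terms=n_terms,
        terms_per_entity=terms_per_entity,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    pool = sorted(scenario.dag.terms - {scenario.dag.root})
    gene_of_term: dict[str, list[str]] = {}
    annotations: list[tuple[str, str]] = []
    for i, term in enumerate(pool):
        genes = [f"g_{i:03d}_{j}" for j in range(genes_per_term)]
        gene_of_term[term] = genes
        annotations += [(g, term) for g in genes]
    null_genes = [f"null_{j:04d}" for j in range(n_null_genes)]
    # null genes are annotated to random terms so they count in the
    # background without being differentially expressed
    for g in null_genes:
        term = pool[int(rng.integers(len(pool)))]
        annotations.append((g, term))
    all_genes = sorted({g for g, _ in annotations})

    def build_profiles(terms: set[str], base_seed: int) -> list[ExpressionProfile]:
        planted = {g for t in terms for g in gene_of_term[t]}
        profiles = []
        shift = effect * noise_sd
        for d in range(n_datasets):
            sub_rng = np.random.default_rng((base_seed + d) % (2**31))
            baseline = sub_rng.uniform(5.0, 10.0, size=len(all_genes))
            log2x = baseline[:, None] + sub_rng.normal(
                0.0, noise_sd, size=(len(all_genes), 10)
            )
            planted_mask = np.array([g in planted for g in all_genes])
            log2x[planted_mask, :5] += shift
            columns = [f"t{i}" for i in range(5)] + [f"c{i}" for i in range(5)]
            labels = pd.Series([TREATMENT] * 5 + [CONTROL] * 5, index=columns)
            profiles.append(
                ExpressionProfile(
                    matrix=pd.DataFrame(log2x, index=all_genes, columns=columns),
                    class_labels=labels,
                    is_log2=True,
                )
            )
        return profiles

    sm_expression = {
        sm: build_profiles(terms, seed + 100 + 10 * i)
        for i, (sm, terms) in enumerate(sorted(scenario.sm_profiles.items()))
    }
    mirna_expression = {
        mir: build_profiles(terms, seed + 10_000 + 10 * i)
        for i, (mir, terms) in enumerate(sorted(scenario.mirna_profiles.items()))
    }
    truth = {
        "planted_pairs": scenario.planted_pairs,
        "sm_terms": {k: sorted(v) for k, v in scenario.sm_profiles.items()},
        "mirna_terms": {k: sorted(v) for k, v in scenario.mirna_profiles.items()},
        "planted_genes": {
            e: sorted({g for t in terms for g in gene_of_term[t]})
            for e, terms in {**scenario.sm_profiles, **scenario.mirna_profiles}.items()
        },
        "params": {**scenario.params, "genes_per_term": genes_per_term,
                   "n_null_genes": n_null_genes, "effect": effect,
                   "noise_sd": noise_sd, "n_datasets": n_datasets},
    }
    return PipelineScenario(
        dag=scenario.dag,
        annotations=annotations,
        sm_expression=sm_expression,
        mirna_expression=mirna_expression,
        truth=truth,
    )
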