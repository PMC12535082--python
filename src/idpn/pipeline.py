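"""End-to-end subtyping pipeline over a feature table.

Glues the stages together: split controls/patients by the NSSI flag, build
the reference network, compute one differential network per patient, count
edge prevalence, select high-prevalence edges, standardize, choose k by
the elbow rule (or use a fixed k), cluster, run the collinearity and
discriminant checks, and compare the resulting groups on edge z-scores and
NSSI severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import FEATURE_NAMES, FLAG_COL, SEVERITY_COL, validate_feature_table
from .group_stats import compare_groups, severity_summary
from .network import IDPN, ReferenceNetwork, batch_idpn, build_reference_network
from .subtyping import (
    ClusterModel,
    edge_prevalence,
    elbow_select_k,
    kmeans_cluster,
    lda_validate,
    patient_z_table,
    select_edges,
    standardize,
    vif_check,
)


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    m_edges: int | None = None  # default: all unique edges (136 for 17 features)
    min_count: int | None = 14
    min_fraction: float | None = None
    k: int | None = None  # None: choose by elbow
    k_range: tuple[int, int] = (1, 8)
    max_iter: int = 40
    restarts: int = 10
    seed: int | None = None
    formula: str = "ratio"
    feature_names: tuple[str, ...] = FEATURE_NAMES


@dataclass
class PipelineResult:
    reference: ReferenceNetwork
    idpns: list[IDPN]
    prevalence: pd.DataFrame
    selected_edges: list[tuple[str, str]]
    z_table: pd.DataFrame  # raw per-patient z-scores on selected edges
    cluster_model: ClusterModel
    vif: pd.DataFrame
    lda: dict
    comparison: pd.DataFrame | None
    severity: dict | None
    config: PipelineConfig = field(repr=False, default=None)


def run_pipeline(table: pd.DataFrame, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full subtyping pipeline on a feature table."""
    cfg = config or PipelineConfig()
    table = validate_feature_table(table, cfg.feature_names)
    controls = table[~table[FLAG_COL]]
    patients = table[table[FLAG_COL]]
    if len(patients) == 0:
        raise ValueError("no NSSI-flagged patients in the table")

    ref = build_reference_network(controls, cfg.feature_names)
    idpns = batch_idpn(
        controls, patients,
        alpha=cfg.alpha, feature_names=cfg.feature_names,
        m_edges=cfg.m_edges, formula=cfg.formula, ref=ref,
    )
    prevalence = edge_prevalence(idpns, ref)
    edges = select_edges(prevalence, min_fraction=cfg.min_fraction, min_count=cfg.min_count)
    z_table = patient_z_table(idpns, ref, edges)
    z_std, _ = standardize(z_table)

    if cfg.k is None:
        k, wss = elbow_select_k(
            z_std, range(cfg.k_range[0], cfg.k_range[1] + 1),
            seed=cfg.seed, restarts=cfg.restarts, max_iter=cfg.max_iter,
        )
    else:
        k, wss = cfg.k, None
    severity = patients[SEVERITY_COL].to_numpy()
    model = kmeans_cluster(
        z_std, k, max_iter=cfg.max_iter, seed=cfg.seed, restarts=cfg.restarts,
        severity=severity, selected_edges=tuple(edges), wss_by_k=wss,
    )
    vif = vif_check(z_std)
    lda = lda_validate(z_std, model.assignments.to_numpy())

    comparison = None
    sev_summary = None
    if k == 2:
        comparison = compare_groups(z_table, model.assignments.to_numpy())
        sev_summary = severity_summary(severity, model.assignments.to_numpy())
    return PipelineResult(
        reference=ref, idpns=idpns, prevalence=prevalence,
        selected_edges=edges, z_table=z_table, cluster_model=model,
        vif=vif, lda=lda, comparison=comparison, severity=sev_summary,
        config=cfg,
    )
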