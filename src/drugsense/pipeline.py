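"""End-to-end orchestration: clustering, per-paired-cluster modeling, baselines.

Thin glue over the other modules so the command-line interface, the test
suite and reproduction scripts all run the identical pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusteringResult, select_k
from .data_io import GeneNetwork, restrict_to_lcc
from .feature_network import (
    FeatureNetwork,
    clean_descriptors,
    drug_distributions,
    graphical_lasso_network,
    select_lambda,
    spearman_reduce,
)
from .network_measure import all_invariant_measures
from .response_models import (
    EvaluationResult,
    PairedClusterDesign,
    assemble_design,
    cdcn_predict,
    concat_evaluate,
    crossval_rf,
    evaluate,
    similarity_weights,
)
from .transport import DistanceMatrix, ground_metric, pairwise_wasserstein

logger = logging.getLogger("drugsense")

__all__ = [
    "cluster_cell_lines",
    "cluster_drugs",
    "DrugClusteringArtifacts",
    "clustered_rf_evaluation",
    "pooled_rf_evaluation",
    "cdcn_evaluation",
]


def cluster_cell_lines(
    expr: pd.DataFrame,
    network: GeneNetwork,
    k_min: int = 2,
    k_max: int = 15,
    epsilon: float | None = None,
) -> tuple[ClusteringResult, DistanceMatrix]:
    """Invariant measures on the network -> pairwise W1 -> silhouette-selected clustering."""
    net = restrict_to_lcc(network, keep=expr.columns)
    measures = all_invariant_measures(expr, net, epsilon=epsilon)
    metric = ground_metric(net)
    D = pairwise_wasserstein(measures, metric, ids=tuple(expr.index))
    result = select_k(D, k_min=k_min, k_max=k_max)
    logger.info("cell lines: k*=%d (mean silhouette %.3f)", result.k, result.mean_silhouette)
    return result, D


@dataclass(frozen=True)
class DrugClusteringArtifacts:
    result: ClusteringResult
    distances: DistanceMatrix
    feature_net: FeatureNetwork
    lcc: GeneNetwork
    scaled_descriptors: pd.DataFrame  # drugs x LCC descriptors, min-max scaled
    lam: float


def cluster_drugs(
    descriptors: pd.DataFrame,
    lam: float | None = None,
    target_count: int | None = None,
    near_constant_frac: float = 0.95,
    k_min: int = 2,
    k_max: int = 15,
) -> DrugClusteringArtifacts:
    """Clean -> (optional Spearman reduction) -> graphical LASSO -> W1 -> clustering."""
    table = clean_descriptors(descriptors, near_constant_frac=near_constant_frac)
    if target_count is not None and target_count < table.shape[1]:
        table, _ = spearman_reduce(table, target_count=target_count)
    if lam is None:
        lam = select_lambda(table)
        logger.info("graphical LASSO penalty selected on grid: lambda=%.4g", lam)
    feature_net = graphical_lasso_network(table, lam)
    measures, lcc = drug_distributions(table, feature_net)
    metric = ground_metric(lcc)
    D = pairwise_wasserstein(measures, metric, ids=tuple(table.index))
    result = select_k(D, k_min=k_min, k_max=k_max)
    logger.info("drugs: k*=%d (mean silhouette %.3f)", result.k, result.mean_silhouette)
    from .feature_network import scale_descriptors

    scaled = scale_descriptors(table[list(lcc.nodes)])
    return DrugClusteringArtifacts(result, D, feature_net, lcc, scaled, float(lam))


def _paired_designs(
    cell_labels: pd.Series,
    drug_labels: pd.Series,
    expr: pd.DataFrame,
    scaled_descriptors: pd.DataFrame,
    responses: pd.DataFrame,
    min_rows: int,
) -> list[PairedClusterDesign]:
    designs = []
    for g in sorted(cell_labels.unique()):
        cells = list(cell_labels.index[cell_labels == g])
        for h in sorted(drug_labels.unique()):
            drugs = list(drug_labels.index[drug_labels == h])
            design = assemble_design(
                cells, drugs, expr, scaled_descriptors, responses, cell_cluster=int(g), drug_cluster=int(h)
            )
            if design.n_rows < min_rows:
                raise ValueError(
                    f"paired cluster ({g}, {h}) has only {design.n_rows} observed pairs"
                )
            designs.append(design)
    return designs


def clustered_rf_evaluation(
    cell_labels: pd.Series,
    drug_labels: pd.Series,
    expr: pd.DataFrame,
    scaled_descriptors: pd.DataFrame,
    responses: pd.DataFrame,
    folds: int = 3,
    trees: int = 100,
    min_leaf: int = 5,
    seed: int = 0,
) -> tuple[list[tuple[PairedClusterDesign, EvaluationResult]], EvaluationResult]:
    """Cross-validated RF per paired cluster plus the concatenated evaluation."""
    designs = _paired_designs(cell_labels, drug_labels, expr, scaled_descriptors, responses, folds * 2)
    per_cluster = []
    for idx, design in enumerate(designs):
        preds = crossval_rf(design, folds=folds, trees=trees, min_leaf=min_leaf, seed=seed + 1000 * idx)
        per_cluster.append((design, evaluate(preds, design.y)))
    overall = concat_evaluate([ev for _, ev in per_cluster])
    return per_cluster, overall


def pooled_rf_evaluation(
    expr: pd.DataFrame,
    scaled_descriptors: pd.DataFrame,
    responses: pd.DataFrame,
    folds: int = 3,
    trees: int = 100,
    min_leaf: int = 5,
    seed: int = 0,
) -> EvaluationResult:
    """Single RF over all observed pairs without prior clustering (comparison arm)."""
    design = assemble_design(
        list(responses.index), list(responses.columns), expr, scaled_descriptors, responses
    )
    preds = crossval_rf(design, folds=folds, trees=trees, min_leaf=min_leaf, seed=seed)
    return evaluate(preds, design.y)


def cdcn_evaluation(
    responses: pd.DataFrame,
    cell_labels: pd.Series,
    drug_labels: pd.Series,
    cells_arg,
    drugs_arg,
    mode: str = "wasserstein-kernel",
) -> EvaluationResult:
    """Leave-one-out CDCN predictions per paired cluster, concatenated.

    ``cells_arg``/``drugs_arg`` are W1 DistanceMatrix objects in
    wasserstein-kernel mode, or raw feature tables in pearson mode.
    """
    weights = similarity_weights(cells_arg, drugs_arg, mode=mode)
    preds_all, obs_all = [], []
    for g in sorted(cell_labels.unique()):
        cells = list(cell_labels.index[cell_labels == g])
        for h in sorted(drug_labels.unique()):
            drugs = list(drug_labels.index[drug_labels == h])
            pred = cdcn_predict(responses, weights, cells, drugs)
            obs = responses.loc[pred.index, pred.columns]
            ok = pred.notna() & obs.notna()
            preds_all.append(pred.to_numpy()[ok.to_numpy()])
            obs_all.append(obs.to_numpy()[ok.to_numpy()])
    return evaluate(np.concatenate(preds_all), np.concatenate(obs_all))
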