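"""End-to-end consensus clustering: weights -> consensus -> graph -> fit -> labels.

``run_pipeline`` executes the whole method on an expression matrix plus M
base partitions; ``sweep`` grid-searches the (b, alpha) hyperparameter pair
against reference labels, reporting ARI and NMI per grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import ClusterAssignment, assign_clusters
from .config import RunConfig
from .ensemble import (
    ConsensusMatrix,
    EnsembleWeights,
    assemble_consensus,
    binarize_consensus,
    calinski_harabasz,
    labels_to_comembership,
    normalize_weights,
)
from .graph import NeighborGraph, knn_graph
from .io import ExpressionMatrix, PartitionLabels, feature_matrix
from .metrics import adjusted_rand_index, normalized_mutual_information
from .model import FitResult, fit

__all__ = ["PipelineResult", "run_pipeline", "sweep"]


@dataclass
class PipelineResult:
    assignment: ClusterAssignment
    fit_result: FitResult
    weights: EnsembleWeights
    consensus: ConsensusMatrix
    graph: NeighborGraph | None
    variant: str  # "graph-regularized" or "unregularized" (alpha = 0)


def _stage(name: str):
    """Re-raise stage failures with the pipeline stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, RuntimeError):
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(
    x: ExpressionMatrix,
    bases: list[PartitionLabels],
    cfg: RunConfig | None = None,
) -> PipelineResult:
    """Run the full method and return labels, cluster count and diagnostics.

    Stages: (1) score each base partition with the Calinski-Harabasz index
    on the expression feature space and normalize into weights; (2) assemble
    the weighted consensus matrix and binarize it at ``cfg.wt``; (3) build
    the KNN graph and Laplacian over the same feature space; (4) fit the
    graph-regularized Bernoulli factorization with multi-restart alternating
    updates; (5) extract argmax labels and the cluster count.
    """
    cfg = cfg or RunConfig()
    if not bases:
        raise ValueError("at least one base partition is required")
    bases = [p.reorder(x.cell_ids) for p in bases]

    with _stage("features"):
        feats = feature_matrix(x, use_pca=cfg.use_pca, n_components=cfg.n_pcs)

    with _stage("weights"):
        if len(bases) == 1:
            weights = EnsembleWeights(
                scores=np.array([1.0]),
                weights=np.array([1.0]),
                method_names=[bases[0].method_name],
            )
        else:
            scores = [
                calinski_harabasz(feats, p, variant=cfg.ch_variant) for p in bases
            ]
            weights = normalize_weights(
                scores, method_names=[p.method_name for p in bases]
            )

    with _stage("consensus"):
        comemberships = [labels_to_comembership(p) for p in bases]
        weighted = assemble_consensus(comemberships, weights)
        consensus = (
            weighted if cfg.use_weighted_consensus else binarize_consensus(weighted, cfg.wt)
        )

    graph = None
    if cfg.alpha != 0.0:
        with _stage("graph"):
            graph = knn_graph(feats, k=cfg.knn_k)

    with _stage("fit"):
        result = fit(consensus, graph, cfg.fit_config())

    with _stage("assign"):
        assignment = assign_clusters(
            result.h_star, prune_tol=cfg.prune_tol, cell_ids=x.cell_ids
        )

    variant = "unregularized" if cfg.alpha == 0.0 else "graph-regularized"
    return PipelineResult(
        assignment=assignment,
        fit_result=result,
        weights=weights,
        consensus=consensus,
        graph=graph,
        variant=variant,
    )


def sweep(
    x: ExpressionMatrix,
    bases: list[PartitionLabels],
    truth: PartitionLabels,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Grid-search (b, alpha); one row per cell with ARI/NMI vs the truth.

    Uses ``cfg.sweep_restarts`` restarts per cell (the full restart count on
    every grid cell would be needlessly slow for a survey).
    """
    cfg = cfg or RunConfig()
    if not cfg.b_grid or not cfg.alpha_grid:
        raise ValueError("b_grid and alpha_grid must be non-empty")
    rows = []
    for b in cfg.b_grid:
        for alpha in cfg.alpha_grid:
            cell_cfg = RunConfig(**{**cfg.__dict__, "hyper_b": b, "alpha": alpha,
                                    "n_restarts": cfg.sweep_restarts})
            result = run_pipeline(x, bases, cell_cfg)
            pred = result.assignment.to_partition()
            rows.append(
                {
                    "b": b,
                    "alpha": alpha,
                    "ari": adjusted_rand_index(pred, truth),
                    "nmi": normalized_mutual_information(pred, truth),
                    "n_clusters": result.assignment.n_clusters,
                    "objective": result.fit_result.objective,
                }
            )
    return pd.DataFrame(rows)
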