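"""Graph-regularized Bernoulli consensus factorization with ARD priors.

The binarized consensus matrix W is modeled edge-wise: for each unordered
pair of cells i < j,

    w_ij ~ Bernoulli(1 - exp(-s_ij)),   s_ij = sum_z h_iz h_jz,

where H is an n x Q nonnegative latent-strength matrix.  Each column z of H
carries a half-normal prior with scale beta_z, and each beta_z an
inverse-Gamma(a, b) hyperprior — the automatic-relevance-determination
mechanism that drives unused columns to zero and thereby selects the number
of clusters.  A k-nearest-neighbor graph over the expression feature space
contributes the manifold penalty alpha * trace(H^T L H), which pulls cells
that are close in expression space toward shared factor profiles even when
the base clusterings disagree about them.

The negative log joint, with additive constants dropped consistently, is

    F(H, beta) = - sum_{i<j} [ w_ij log(1 - e^{-s_ij}) - (1 - w_ij) s_ij ]
                 + sum_z [ sum_i h_iz^2 / (2 beta_z) + (n/2) log beta_z ]
                 + sum_z [ (a+1) log beta_z + b / beta_z ]
                 + (alpha / 2) * trace(H^T L H).

F is minimized by alternating a damped multiplicative update of H

    h_iz <- 1/2 h_iz + 1/2 h_iz * N_iz / D_iz,
    N_iz = sum_{j != i} w_ij h_jz / (1 - e^{-s_ij}) + alpha sum_j v_ij h_jz,
    D_iz = sum_{j != i} h_jz + h_iz / beta_z + alpha d_i h_iz,

with the exact coordinate-wise minimizer of F over beta,

    beta_z <- (2b + sum_i h_iz^2) / (n + 2a + 2).

The 1/2 on the graph penalty makes the alpha terms of the update the exact
split of the penalty gradient alpha * (L H) into its negative (adjacency)
and positive (degree) parts, so N - D equals minus the gradient of F in H
and fixed points of the update are stationary points of the objective; with
the penalty counted at full weight the same iteration corresponds to
doubling alpha.  Iteration stops when the beta vector
moves less than ``rho`` between sweeps or after ``max_iter`` sweeps; the fit
is restarted from ``n_restarts`` random initializations and the restart with
the lowest objective wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ensemble import ConsensusMatrix
from .graph import NeighborGraph, graph_penalty

__all__ = [
    "FitConfig",
    "FitResult",
    "init_factors",
    "objective",
    "update_h",
    "update_beta",
    "fit",
]

logger = logging.getLogger(__name__)

EPS = 1e-12  # floor for 1 - e^{-s} and for update denominators


@dataclass
class FitConfig:
    """Hyperparameters and stopping rules for the factorization.

    Defaults: Q = 25 latent columns (an upper bound on the cluster count,
    shrunk by ARD), graph weight alpha = 100, inverse-Gamma shape a = 1 and
    scale b = 0.3, beta-convergence threshold rho = 1e-5, at most 100 sweeps,
    50 random restarts.
    """

    q_max: int = 25
    alpha: float = 100.0
    hyper_a: float = 1.0
    hyper_b: float = 0.3
    rho: float = 1e-5
    max_iter: int = 100
    n_restarts: int = 50
    seed: int = 0
    prune_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.q_max < 1 or self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("q_max, max_iter and n_restarts must be >= 1")
        if self.alpha < 0 or self.rho <= 0 or self.hyper_a <= 0 or self.hyper_b <= 0:
            raise ValueError("alpha must be >= 0; rho, a, b must be > 0")


@dataclass
class FitResult:
    """Best restart of the alternating optimization."""

    h_star: np.ndarray
    beta: np.ndarray
    objective: float
    objective_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    restart_index: int = 0
    converged: bool = False


def init_factors(n: int, q_max: int, seed: int) -> np.ndarray:
    """Random H with entries uniform on (0.01, 1.0); deterministic per seed."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.01, 1.0, size=(n, q_max))


def _consensus_values(w: ConsensusMatrix | np.ndarray) -> np.ndarray:
    return w.values if isinstance(w, ConsensusMatrix) else np.asarray(w, dtype=float)


def _edge_prob(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """S = H H^T and the Bernoulli parameter 1 - e^{-S}, stably via expm1."""
    s = h @ h.T
    return s, -np.expm1(-s)


def objective(
    w: ConsensusMatrix | np.ndarray,
    h: np.ndarray,
    beta: np.ndarray,
    g: NeighborGraph | None,
    alpha: float,
    hyper_a: float = 1.0,
    hyper_b: float = 0.3,
) -> float:
    """Negative log joint F(H, beta) plus the graph penalty (constants dropped)."""
    wv = _consensus_values(w)
    h = np.asarray(h, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = h.shape[0]
    if wv.shape != (n, n):
        raise ValueError("consensus matrix and H disagree on cell count")
    if np.any(beta <= 0):
        raise ValueError("beta must be strictly positive")
    s, prob = _edge_prob(h)
    iu = np.triu_indices(n, k=1)  # unordered pairs, diagonal excluded
    log_prob = np.log(np.maximum(prob[iu], EPS))
    neg_loglik = -float(np.sum(wv[iu] * log_prob - (1.0 - wv[iu]) * s[iu]))
    neg_logprior_h = float(
        np.sum(np.sum(h**2, axis=0) / (2.0 * beta) + (n / 2.0) * np.log(beta))
    )
    neg_logprior_beta = float(
        np.sum((hyper_a + 1.0) * np.log(beta) + hyper_b / beta)
    )
    value = neg_loglik + neg_logprior_h + neg_logprior_beta
    if alpha != 0.0:
        if g is None:
            raise ValueError("alpha > 0 requires a neighbor graph")
        # 1/2 pairs the objective with the multiplicative rule's alpha scale
        value += 0.5 * alpha * graph_penalty(h, g)
    return value


def update_h(
    w: ConsensusMatrix | np.ndarray,
    h: np.ndarray,
    beta: np.ndarray,
    g: NeighborGraph | None,
    alpha: float,
) -> np.ndarray:
    """One damped multiplicative sweep; preserves nonnegativity and zeros."""
    wv = _consensus_values(w)
    h = np.asarray(h, dtype=float)
    beta = np.asarray(beta, dtype=float)
    _, prob = _edge_prob(h)
    ratio = wv / np.maximum(prob, EPS)
    np.fill_diagonal(ratio, 0.0)  # likelihood runs over pairs i != j
    numer = ratio @ h
    denom = (h.sum(axis=0)[None, :] - h) + h / beta[None, :]
    if alpha != 0.0:
        if g is None:
            raise ValueError("alpha > 0 requires a neighbor graph")
        # exact gradient split of (alpha/2) tr(H^T L H): alpha L H
        numer = numer + alpha * (g.adjacency @ h)
        denom = denom + alpha * g.degrees[:, None] * h
    return 0.5 * h + 0.5 * h * numer / np.maximum(denom, EPS)


def update_beta(h: np.ndarray, hyper_a: float = 1.0, hyper_b: float = 0.3) -> np.ndarray:
    """Exact minimizer of F over beta: beta_z = (2b + sum_i h_iz^2) / (n + 2a + 2)."""
    h = np.asarray(h, dtype=float)
    n = h.shape[0]
    return (2.0 * hyper_b + np.sum(h**2, axis=0)) / (n + 2.0 * hyper_a + 2.0)


def _fit_single(
    wv: np.ndarray, g: NeighborGraph | None, cfg: FitConfig, seed: int
) -> FitResult:
    n = wv.shape[0]
    h = init_factors(n, cfg.q_max, seed)
    beta = update_beta(h, cfg.hyper_a, cfg.hyper_b)
    trace: list[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, cfg.max_iter + 1):
        h = update_h(wv, h, beta, g, cfg.alpha)
        beta_new = update_beta(h, cfg.hyper_a, cfg.hyper_b)
        obj = objective(wv, h, beta_new, g, cfg.alpha, cfg.hyper_a, cfg.hyper_b)
        trace.append(obj)
        if not np.isfinite(obj):
            raise FloatingPointError(f"non-finite objective at iteration {iteration}")
        delta = float(np.linalg.norm(beta_new - beta))
        beta = beta_new
        if delta < cfg.rho:
            converged = True
            break
    return FitResult(
        h_star=h,
        beta=beta,
        objective=trace[-1],
        objective_trace=trace,
        n_iterations=iteration,
        converged=converged,
    )


def fit(
    w: ConsensusMatrix | np.ndarray,
    g: NeighborGraph | None,
    cfg: FitConfig,
) -> FitResult:
    """Multi-restart alternating optimization; returns the lowest-objective restart.

    Restart r initializes H from seed ``cfg.seed + r``.  A restart whose
    objective turns non-finite is dropped with a logged diagnostic; if every
    restart fails, a RuntimeError is raised.
    """
    wv = _consensus_values(w)
    if wv.shape[0] != wv.shape[1]:
        raise ValueError("consensus matrix must be square")
    if not np.allclose(wv, wv.T):
        raise ValueError("consensus matrix must be symmetric")
    if isinstance(w, ConsensusMatrix) and not w.binarized:
        logger.warning("fitting a non-binarized consensus matrix")
    best: FitResult | None = None
    for r in range(cfg.n_restarts):
        try:
            result = _fit_single(wv, g, cfg, cfg.seed + r)
        except FloatingPointError as exc:
            logger.warning("restart %d aborted: %s", r, exc)
            continue
        result.restart_index = r
        if best is None or result.objective < best.objective:
            best = result
    if best is None:
        raise RuntimeError("all restarts failed with non-finite objectives")
    return best
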