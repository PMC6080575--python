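"""Stage-evolving non-negative orthogonal factorization of network sequences.

The model
---------
Let X = [x_1 ... x_tau] collect the vectorized networks (M connections per
time point) and let a stage partition reorganize the columns into G blocks
X^1 ... X^G.  Each stage block is approximated by a non-negative product

    X^t ~= U^t (V^t)^T,        (U^t)^T U^t = I,   U^t >= 0,  V >= 0,

where U^t (M x p) holds the stage-t states of p meta-networks — evolving
connectivity components — and the shared trajectory matrix V (tau x p)
gives each component's loading at every time point, with V^t = (H^t)^T V
selecting stage-t rows through binary mask matrices H^t.  The near-
orthogonality of U^t columns discourages overlapping components, and the
nuclear-norm surrogate of the per-stage product reduces (up to constants
fixed by the orthogonality constraint) to a ridge penalty on V.  The fitted
objective is

    J = sum_t 1/2 ||X^t - U^t V^t'||_F^2 + lambda/2 ||V||_F^2
        + alpha/4 sum_{k,l} W_U(k,l) ||U^k - U^l||_F^2
        + beta/4  sum_{i,j} W_V(i,j) ||v_i - v_j||^2,

with chain-graph adjacencies W_U over chronologically consecutive stages
and W_V over consecutive time points: nervous systems change smoothly, so
both the component states and their trajectories are encouraged to vary
slowly in time.

Optimization is by multiplicative updates that preserve non-negativity and
leave exact factorizations fixed:

    U^t <- U^t . sqrt( [X^t V^t + alpha sum_k W_U(t,k) U^k]
               / [U^t (V^t' X^t' U^t) + alpha sum_k W_U(t,k) U^t U^t' U^k] )

    V   <- V . [sum_t H^t X^t' U^t + beta W_V V]
             / [sum_t H^t H^t' V U^t' U^t + lambda V + beta D_V V]

(elementwise product/division; D_V the degree matrix of W_V; a small
epsilon guards every denominator).  The element-wise square root on the U
multiplier is the standard damping of Lagrangian-constrained multiplicative
rules: it has exactly the same fixed points as the raw ratio but removes
the period-two overshoot the raw ratio exhibits, making the objective
empirically non-increasing.  The number of components p is selected
by maximizing the Minimal Trajectory Distance, the smallest pairwise
Euclidean distance among L2-normalized trajectory columns: the larger the
MTD, the more separable — and the more interpretable — the components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ParameterError, ValidationError
from .networks import DevelopmentalNetworks
from .stages import StagePartition

__all__ = [
    "SmoothnessGraphs",
    "DMDConfig",
    "DMDResult",
    "build_smoothness_graphs",
    "stage_masks",
    "split_blocks",
    "objective",
    "update_U",
    "update_V",
    "fit",
    "compute_mtd",
    "select_num_dms",
]

logger = logging.getLogger(__name__)


@dataclass
class SmoothnessGraphs:
    """Chain adjacencies for temporal smoothing of U (stages) and V (time)."""

    W_U: np.ndarray  # G x G, symmetric, zero diagonal
    W_V: np.ndarray  # tau x tau, symmetric, zero diagonal

    @property
    def D_V(self) -> np.ndarray:
        return np.diag(self.W_V.sum(axis=1))


@dataclass
class DMDConfig:
    """Hyperparameters of the factorization.

    lambda (``lam``) weighs the ridge on V that stands in for the nuclear
    norm of each stage product; ``alpha`` and ``beta`` weigh the stage- and
    time-smoothness terms.  All three default to 0.1 — the method is robust
    over a wide range, and these sit in the middle of it.  ``n_init``
    random restarts are run and the one with the least final objective is
    kept, mirroring k-means practice.
    """

    p: int = 4
    lam: float = 0.1
    alpha: float = 0.1
    beta: float = 0.1
    n_init: int = 100
    max_iter: int = 1000
    tol: float = 1e-6
    epsilon: float = 1e-12
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ParameterError("p must be >= 1")
        if min(self.lam, self.alpha, self.beta) < 0:
            raise ParameterError("lambda, alpha, beta must be >= 0")
        if self.tol <= 0:
            raise ParameterError("tol must be > 0")


@dataclass
class DMDResult:
    """Fitted meta-networks, trajectories and optimization diagnostics."""

    U: list  # G arrays of shape (M, p)
    V: np.ndarray  # tau x p
    objective_trace: np.ndarray
    orthogonality_gap: list  # per stage ||U^t' U^t - I||_F
    chosen_restart: int
    final_objective: float
    partition: StagePartition | None = None
    config: DMDConfig | None = None

    @property
    def p(self) -> int:
        return self.V.shape[1]

    def stacked_states(self, r: int) -> np.ndarray:
        """States of component r across stages as an (M, G) matrix."""
        return np.column_stack([Ut[:, r] for Ut in self.U])


def _chain(n: int) -> np.ndarray:
    W = np.zeros((n, n))
    idx = np.arange(n - 1)
    W[idx, idx + 1] = 1.0
    W[idx + 1, idx] = 1.0
    return W


def build_smoothness_graphs(
    partition: StagePartition, time_labels=None
) -> SmoothnessGraphs:
    """Chain graphs: unit weight between consecutive stages / time points."""
    return SmoothnessGraphs(W_U=_chain(partition.G), W_V=_chain(partition.tau))


def stage_masks(partition: StagePartition) -> list[np.ndarray]:
    """Binary mask matrices H^t (tau x n_t) with V^t = H^t' V."""
    tau = partition.tau
    masks = []
    for block in partition.blocks:
        H = np.zeros((tau, len(block)))
        H[block, np.arange(len(block))] = 1.0
        masks.append(H)
    return masks


def split_blocks(X: np.ndarray, partition: StagePartition) -> list[np.ndarray]:
    """Stage blocks X^t (M x n_t) in chronological stage order."""
    return [X[:, block] for block in partition.blocks]


def _check_nonneg(*arrays: np.ndarray) -> None:
    for a in arrays:
        if np.any(np.asarray(a) < 0):
            raise ValidationError("factor matrices and data must be non-negative")


def objective(
    X: np.ndarray,
    partition: StagePartition,
    U: list[np.ndarray],
    V: np.ndarray,
    graphs: SmoothnessGraphs,
    config: DMDConfig,
) -> float:
    """Evaluate J for the current factors (see module docstring)."""
    blocks = split_blocks(np.asarray(X, dtype=float), partition)
    if len(U) != partition.G or V.shape[0] != partition.tau:
        raise ValidationError("U/V shapes inconsistent with the stage partition")
    J = 0.0
    for t, Xt in enumerate(blocks):
        Vt = V[partition.blocks[t], :]
        if U[t].shape != (Xt.shape[0], V.shape[1]):
            raise ValidationError(
                f"stage {t}: U has shape {U[t].shape}, expected "
                f"({Xt.shape[0]}, {V.shape[1]})"
            )
        J += 0.5 * np.sum((Xt - U[t] @ Vt.T) ** 2)
    J += 0.5 * config.lam * np.sum(V**2)
    if config.alpha > 0:
        for k in range(partition.G):
            for l in range(partition.G):
                w = graphs.W_U[k, l]
                if w:
                    J += 0.25 * config.alpha * w * np.sum((U[k] - U[l]) ** 2)
    if config.beta > 0:
        for i in range(partition.tau):
            for j in range(partition.tau):
                w = graphs.W_V[i, j]
                if w:
                    J += 0.25 * config.beta * w * np.sum((V[i] - V[j]) ** 2)
    return float(J)


def update_U(
    blocks: list[np.ndarray],
    U: list[np.ndarray],
    V: np.ndarray,
    partition: StagePartition,
    graphs: SmoothnessGraphs,
    config: DMDConfig,
    exponent: float = 0.5,
) -> list[np.ndarray]:
    """One multiplicative sweep over the stage states U^1 ... U^G.

    Stages are updated sequentially, each using the latest states of its
    neighbours.  The multiplier is raised to ``exponent`` element-wise
    (1/2 by default — the standard damping of Lagrangian-constrained
    multiplicative rules; any positive exponent has the same fixed
    points).  Zeros stay zero and non-negativity is preserved.
    """
    _check_nonneg(V, *U, *blocks)
    eps = config.epsilon
    U = [Ut.copy() for Ut in U]
    for t in range(partition.G):
        Xt = blocks[t]
        Vt = V[partition.blocks[t], :]
        numer = Xt @ Vt
        denom = U[t] @ (Vt.T @ (Xt.T @ U[t]))
        if config.alpha > 0:
            for k in range(partition.G):
                w = graphs.W_U[t, k]
                if w:
                    numer = numer + config.alpha * w * U[k]
                    denom = denom + config.alpha * w * (U[t] @ (U[t].T @ U[k]))
        U[t] = U[t] * (numer / (denom + eps)) ** exponent
    return U


def update_V(
    blocks: list[np.ndarray],
    U: list[np.ndarray],
    V: np.ndarray,
    partition: StagePartition,
    graphs: SmoothnessGraphs,
    config: DMDConfig,
) -> np.ndarray:
    """One global multiplicative update of the trajectory matrix V."""
    _check_nonneg(V, *U, *blocks)
    eps = config.epsilon
    numer = np.zeros_like(V)
    denom = config.lam * V
    for t, block in enumerate(partition.blocks):
        # H^t X^t' U^t scatters the stage rows; H^t H^t' V selects them
        numer[block, :] += blocks[t].T @ U[t]
        denom[block, :] += V[block, :] @ (U[t].T @ U[t])
    if config.beta > 0:
        numer = numer + config.beta * (graphs.W_V @ V)
        denom = denom + config.beta * (graphs.W_V.sum(axis=1)[:, None] * V)
    return V * numer / (denom + eps)


def _init_factors(
    blocks: list[np.ndarray],
    partition: StagePartition,
    p: int,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Random positive factors at a comparable objective scale.

    U^t columns are drawn uniform on (0, 1] and normalized to unit length;
    V is drawn uniform and rescaled by the global least-squares constant
    matching the reconstruction to ||X||.
    """
    M = blocks[0].shape[0]
    tau = partition.tau
    U = []
    for _ in range(partition.G):
        Ut = 1.0 - rng.random((M, p))
        Ut /= np.linalg.norm(Ut, axis=0, keepdims=True)
        U.append(Ut)
    V = 1.0 - rng.random((tau, p))
    num = 0.0
    den = 0.0
    for t, block in enumerate(partition.blocks):
        recon = U[t] @ V[block, :].T
        num += np.sum(blocks[t] * recon)
        den += np.sum(recon**2)
    if den > 0 and num > 0:
        V *= num / den
    return U, V


def fit(
    X: DevelopmentalNetworks | np.ndarray,
    partition: StagePartition,
    config: DMDConfig,
) -> DMDResult:
    """Alternate the multiplicative updates from random restarts.

    Each restart iterates update_U / update_V until the relative objective
    change drops below ``config.tol`` or ``config.max_iter`` is reached;
    the restart with the least final objective is returned.  Deterministic
    given ``config.seed``.
    """
    data = X.X if isinstance(X, DevelopmentalNetworks) else np.asarray(X, dtype=float)
    if np.any(data < 0):
        raise ValidationError("X must be non-negative")
    if partition.tau != data.shape[1]:
        raise ValidationError("partition covers a different number of time points")
    if config.p > data.shape[0] or config.p > data.shape[1]:
        raise ParameterError(
            f"p={config.p} exceeds the data dimensions (M={data.shape[0]}, "
            f"tau={data.shape[1]})"
        )
    min_nt = min(partition.sizes)
    if config.p > min_nt:
        # identifiable only through the cross-stage coupling; legal but noted
        logger.info(
            "p=%d exceeds the smallest stage size %d; stage-local states are "
            "over-parameterized and rely on the smoothness coupling",
            config.p,
            min_nt,
        )
    graphs = build_smoothness_graphs(partition)
    blocks = split_blocks(data, partition)
    ss = (
        np.random.SeedSequence(config.seed)
        if config.seed is not None
        else np.random.SeedSequence()
    )
    best: DMDResult | None = None
    for restart, child in enumerate(ss.spawn(config.n_init)):
        rng = np.random.default_rng(child)
        U, V = _init_factors(blocks, partition, config.p, rng)
        trace = [objective(data, partition, U, V, graphs, config)]
        for _ in range(config.max_iter):
            # U sweep with a descent safeguard: if the damped multiplicative
            # step overshoots (possible far from the orthogonality
            # manifold), retry with a smaller exponent — same fixed points —
            # and as a last resort keep the previous state for this sweep.
            J_prev = trace[-1]
            for exponent in (0.5, 0.25, 0.125):
                U_cand = update_U(
                    blocks, U, V, partition, graphs, config, exponent=exponent
                )
                if (
                    objective(data, partition, U_cand, V, graphs, config)
                    <= J_prev
                ):
                    U = U_cand
                    break
            V = update_V(blocks, U, V, partition, graphs, config)
            J = objective(data, partition, U, V, graphs, config)
            trace.append(J)
            if J_prev > 0 and abs(J_prev - J) / J_prev < config.tol:
                break
        final = trace[-1]
        if best is None or final < best.final_objective:
            gaps = [
                float(np.linalg.norm(Ut.T @ Ut - np.eye(config.p))) for Ut in U
            ]
            best = DMDResult(
                U=U,
                V=V,
                objective_trace=np.asarray(trace),
                orthogonality_gap=gaps,
                chosen_restart=restart,
                final_objective=final,
                partition=partition,
                config=config,
            )
    assert best is not None
    return best


def compute_mtd(V: np.ndarray) -> float:
    """Minimal Trajectory Distance of the trajectory columns.

    Columns are L2-normalized so the criterion is comparable across
    different component counts; the distance is plain Euclidean on the
    normalized columns (sqrt(2) for orthogonal trajectories, 0 for
    proportional ones).
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[1] < 2:
        raise ParameterError("MTD requires at least two trajectory columns")
    norms = np.linalg.norm(V, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    Vn = V / safe
    return float(
        min(
            np.linalg.norm(Vn[:, r] - Vn[:, s])
            for r, s in combinations(range(V.shape[1]), 2)
        )
    )


def select_num_dms(
    X: DevelopmentalNetworks | np.ndarray,
    partition: StagePartition,
    p_range,
    config: DMDConfig,
) -> tuple[int, dict[int, float], dict[int, DMDResult]]:
    """Fit each candidate p and pick the one maximizing MTD (ties -> smallest p)."""
    p_list = sorted(set(int(p) for p in p_range))
    if not p_list or p_list[0] < 2:
        raise ParameterError("p_range must contain integers >= 2")
    curve: dict[int, float] = {}
    fits: dict[int, DMDResult] = {}
    for p in p_list:
        cfg = DMDConfig(
            p=p,
            lam=config.lam,
            alpha=config.alpha,
            beta=config.beta,
            n_init=config.n_init,
            max_iter=config.max_iter,
            tol=config.tol,
            epsilon=config.epsilon,
            seed=config.seed,
        )
        res = fit(X, partition, cfg)
        fits[p] = res
        curve[p] = compute_mtd(res.V)
    best = max(curve.values())
    p_star = min(p for p, v in curve.items() if v >= best - 1e-12)
    return p_star, curve, fits
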