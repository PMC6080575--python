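"""Split-half reproducibility of meta-networks and trajectories.

The network sequence is split into odd-positioned and even-positioned time
points (for integer ages 3-20: ages 3, 5, ..., 19 versus 4, 6, ..., 20),
each half is decomposed independently, and the resulting components are
matched one-to-one with the Hungarian algorithm on cosine similarity.  A
component is treated as a unit — its stage states are concatenated into a
single vector — and trajectories are compared under the same matching.
Cosine similarity judges orientation rather than magnitude, which is what
is wanted when the two halves are offset by one year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .dmd import DMDConfig, DMDResult, fit
from .errors import ParameterError, ValidationError
from .networks import DevelopmentalNetworks
from .stages import StagePartition

__all__ = [
    "SplitPair",
    "MatchResult",
    "split_half",
    "match_components",
    "reproducibility_scores",
    "split_half_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitPair:
    """The two interleaved halves of a network sequence with inherited stages."""

    half_A: DevelopmentalNetworks
    half_B: DevelopmentalNetworks
    partition_A: StagePartition
    partition_B: StagePartition


@dataclass
class MatchResult:
    """Hungarian matching of two component sets with per-pair similarities."""

    permutation: np.ndarray  # component r of A matches permutation[r] of B
    u_similarities: np.ndarray
    mean_u_similarity: float


def _restrict_partition(labels: np.ndarray, idx: np.ndarray) -> StagePartition:
    """Stage labels inherited by a half; empty stages merge with a neighbour."""
    sub = labels[idx]
    present = []
    for lab in labels:  # chronological order of the full sequence
        if lab in sub and lab not in present:
            present.append(lab)
    missing = set(labels) - set(sub)
    if missing:
        logger.warning(
            "stages %s are empty in one half and merge with their neighbours",
            sorted(int(m) for m in missing),
        )
    remap = {lab: i for i, lab in enumerate(present)}
    return StagePartition(G=len(present), labels=np.asarray([remap[lab] for lab in sub]))


def split_half(X: DevelopmentalNetworks, partition: StagePartition) -> SplitPair:
    """Odd-positioned time points -> half A, even-positioned -> half B.

    Each half inherits the full-sequence stage labels restricted to its
    time points (stages are not re-estimated, so the comparison isolates
    the factorization's reproducibility).  Requires tau >= 4 so both
    halves have at least two time points.
    """
    if X.tau < 4:
        raise ParameterError(f"split-half requires tau >= 4, got {X.tau}")
    if partition.tau != X.tau:
        raise ValidationError("partition does not cover the network sequence")
    idx_A = np.arange(0, X.tau, 2)
    idx_B = np.arange(1, X.tau, 2)
    half_A = DevelopmentalNetworks(
        X=X.X[:, idx_A],
        N=X.N,
        time_labels=[X.time_labels[i] for i in idx_A],
        node_names=X.node_names,
    )
    half_B = DevelopmentalNetworks(
        X=X.X[:, idx_B],
        N=X.N,
        time_labels=[X.time_labels[i] for i in idx_B],
        node_names=X.node_names,
    )
    return SplitPair(
        half_A=half_A,
        half_B=half_B,
        partition_A=_restrict_partition(partition.labels, idx_A),
        partition_B=_restrict_partition(partition.labels, idx_B),
    )


def _stack_components(U: list[np.ndarray]) -> np.ndarray:
    """Each component's stage states concatenated into one column: (M*G, p)."""
    return np.vstack(U)


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    na = np.where(na > 0, na, 1.0)
    nb = np.where(nb > 0, nb, 1.0)
    return (A / na).T @ (B / nb)


def match_components(U_A: list[np.ndarray], U_B: list[np.ndarray]) -> MatchResult:
    """Optimal one-to-one matching maximizing total cosine similarity."""
    SA = _stack_components(U_A)
    SB = _stack_components(U_B)
    if SA.shape != SB.shape:
        raise ParameterError(
            f"component sets have incompatible shapes {SA.shape} vs {SB.shape}"
        )
    sim = _cosine_matrix(SA, SB)
    rows, cols = linear_sum_assignment(-sim)
    perm = cols[np.argsort(rows)]
    sims = sim[np.arange(len(perm)), perm]
    return MatchResult(
        permutation=perm,
        u_similarities=sims,
        mean_u_similarity=float(sims.mean()),
    )


def reproducibility_scores(
    result_A: DMDResult, result_B: DMDResult
) -> tuple[float, float, pd.DataFrame]:
    """Mean matched cosine similarity of components and of trajectories.

    Components are matched by :func:`match_components`; trajectory columns
    are then compared pairwise under the same permutation (the halves have
    equal length, offset by one time step).
    """
    if result_A.p != result_B.p:
        raise ParameterError("both halves must be decomposed with the same p")
    match = match_components(result_A.U, result_B.U)
    v_sim = np.array(
        [
            _cosine_matrix(
                result_A.V[:, [r]], result_B.V[:, [match.permutation[r]]]
            )[0, 0]
            for r in range(result_A.p)
        ]
    )
    table = pd.DataFrame(
        {
            "component_A": np.arange(result_A.p),
            "component_B": match.permutation,
            "u_cosine": match.u_similarities,
            "v_cosine": v_sim,
        }
    )
    return float(match.u_similarities.mean()), float(v_sim.mean()), table


def split_half_experiment(
    X: DevelopmentalNetworks,
    partition: StagePartition,
    config: DMDConfig,
    reestimate_stages: bool = False,
    n_runs: int = 100,
) -> tuple[float, float, pd.DataFrame]:
    """Decompose both halves independently and score their agreement.

    With ``reestimate_stages`` the stage partition of each half is re-run
    from scratch instead of inherited, folding clustering variability into
    the reproducibility estimate.
    """
    pair = split_half(X, partition)
    if reestimate_stages:
        from .stages import select_stage_partition

        g_range = range(2, min(partition.G + 2, pair.half_A.tau) + 1)
        pair.partition_A, _ = select_stage_partition(
            pair.half_A, g_range, n_runs=n_runs, seed=config.seed
        )
        pair.partition_B, _ = select_stage_partition(
            pair.half_B, g_range, n_runs=n_runs, seed=config.seed
        )
    res_A = fit(pair.half_A, pair.partition_A, config)
    res_B = fit(pair.half_B, pair.partition_B, config)
    return reproducibility_scores(res_A, res_B)
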