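"""Stable and rapidly-changing connections of fitted meta-networks.

A meta-network's *stable connections* are its backbone: edges whose
strength barely changes across stages.  Per edge m of component r, with
stage states collected in an (M, G) matrix U_r, the normalized divergence

    Omega_m = [sum over ordered stage pairs (k, l) of |U_r(m,k) - U_r(m,l)|]
              / [mean over stages of U_r(m, .)]

ranks edges from most to least stable (each unordered pair counts twice —
the factor 2 never changes the ranking).  Insignificant edges with mean
strength below the adaptive threshold delta_r — the root mean square of all
G*M entries of U_r — are excluded, and the top fraction (2% by default) of
surviving edges with the least divergence is reported.

*Rapidly-changing connections* mark the largest per-edge strength changes
Delta u between adjacent stages that move in the same direction as the
component's stage contribution Delta v-bar (the change in its within-stage
mean trajectory): a component that is gaining influence reports its most
strengthened edges, a fading one its most weakened.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dmd import DMDResult
from .errors import ParameterError
from .stages import StagePartition

__all__ = [
    "StableConnectionReport",
    "RapidChangeReport",
    "normalized_divergence",
    "strength_threshold",
    "stable_connections",
    "stage_contributions",
    "rapidly_changing_connections",
    "characterize_result",
]

logger = logging.getLogger(__name__)

DEFAULT_TOP_FRACTION = 0.02


@dataclass
class StableConnectionReport:
    """Ranked stability report for one meta-network."""

    component: int
    omega: np.ndarray  # per-edge normalized divergence (inf where mean is 0)
    mean_strength: np.ndarray  # per-edge mean strength over stages
    threshold: float  # RMS threshold delta_r
    ranking: np.ndarray  # survivor edge indices, most stable first
    selected: np.ndarray  # top-fraction prefix of the ranking


@dataclass
class RapidChangeReport:
    """Per-transition increased/decreased edge sets for one meta-network."""

    component: int
    delta_u: np.ndarray  # (M, G-1) per-edge changes across adjacent stages
    delta_vbar: np.ndarray  # (G-1,) stage-contribution changes
    increased: dict = field(default_factory=dict)  # transition -> edge indices
    decreased: dict = field(default_factory=dict)


def normalized_divergence(U_r: np.ndarray) -> np.ndarray:
    """Per-edge divergence over stages, normalized by the mean strength.

    Edges with zero mean strength receive +inf (never stable) rather than
    raising — an all-zero edge simply cannot be ranked.
    """
    U_r = np.asarray(U_r, dtype=float)
    if U_r.ndim != 2 or U_r.shape[1] < 2:
        raise ParameterError("divergence needs at least two stage states")
    G = U_r.shape[1]
    div = np.zeros(U_r.shape[0])
    for k in range(G):
        for l in range(G):
            div += np.abs(U_r[:, k] - U_r[:, l])
    mean = U_r.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(mean > 0, div / mean, np.inf)
    # constant zero edges have div 0 and mean 0: still excluded
    return omega


def strength_threshold(U_r: np.ndarray) -> float:
    """Quadratic mean (RMS) of all entries of U_r: delta_r = sqrt(||U_r||_F^2 / (G M))."""
    U_r = np.asarray(U_r, dtype=float)
    return float(np.sqrt(np.mean(U_r**2)))


def stable_connections(
    U_r: np.ndarray,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    component: int = 0,
) -> StableConnectionReport:
    """Select the least-divergent edges above the RMS strength threshold.

    Edges with mean strength below delta_r are excluded first; the
    survivors are ranked by ascending divergence (ties broken toward the
    stronger edge) and the first floor(top_fraction * M) are selected —
    fewer if the exclusion leaves less.
    """
    U_r = np.asarray(U_r, dtype=float)
    M = U_r.shape[0]
    omega = normalized_divergence(U_r)
    mean = U_r.mean(axis=1)
    delta = strength_threshold(U_r)
    survivors = np.flatnonzero((mean >= delta) & np.isfinite(omega))
    # ascending omega, ties -> larger mean strength first
    order = np.lexsort((-mean[survivors], omega[survivors]))
    ranking = survivors[order]
    n_select = min(int(np.floor(top_fraction * M)), len(ranking))
    selected = ranking[:n_select]
    if len(ranking) == 0:
        logger.warning(
            "component %d: no edge survives the strength threshold %.4g",
            component,
            delta,
        )
    return StableConnectionReport(
        component=component,
        omega=omega,
        mean_strength=mean,
        threshold=delta,
        ranking=ranking,
        selected=selected,
    )


def stage_contributions(V: np.ndarray, partition: StagePartition) -> np.ndarray:
    """Within-stage means of the trajectories: (G, p) matrix v-bar."""
    V = np.asarray(V, dtype=float)
    return np.vstack([V[block, :].mean(axis=0) for block in partition.blocks])


def rapidly_changing_connections(
    U_r: np.ndarray,
    vbar_r: np.ndarray,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    component: int = 0,
) -> RapidChangeReport:
    """Edges whose change agrees in sign with the stage-contribution change.

    For each adjacent-stage transition t -> t+1: if the component's stage
    contribution rises, report the floor(top_fraction * M) most-increased
    edges (Delta u > 0); if it falls, the most-decreased (Delta u < 0); an
    exactly-zero contribution change reports nothing.
    """
    U_r = np.asarray(U_r, dtype=float)
    vbar_r = np.asarray(vbar_r, dtype=float).ravel()
    if U_r.shape[1] < 2:
        raise ParameterError("rapid-change analysis needs at least two stages")
    if vbar_r.shape[0] != U_r.shape[1]:
        raise ParameterError("stage contributions must have one entry per stage")
    M, G = U_r.shape
    k = int(np.floor(top_fraction * M))
    delta_u = np.diff(U_r, axis=1)
    delta_vbar = np.diff(vbar_r)
    increased: dict[int, np.ndarray] = {}
    decreased: dict[int, np.ndarray] = {}
    for t in range(G - 1):
        du = delta_u[:, t]
        if delta_vbar[t] > 0:
            pos = np.flatnonzero(du > 0)
            top = pos[np.argsort(-du[pos], kind="stable")][:k]
            increased[t] = top
            decreased[t] = np.asarray([], dtype=int)
        elif delta_vbar[t] < 0:
            neg = np.flatnonzero(du < 0)
            top = neg[np.argsort(du[neg], kind="stable")][:k]
            decreased[t] = top
            increased[t] = np.asarray([], dtype=int)
        else:
            increased[t] = np.asarray([], dtype=int)
            decreased[t] = np.asarray([], dtype=int)
    return RapidChangeReport(
        component=component,
        delta_u=delta_u,
        delta_vbar=delta_vbar,
        increased=increased,
        decreased=decreased,
    )


def characterize_result(
    result: DMDResult,
    partition: StagePartition | None = None,
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> tuple[list[StableConnectionReport], list[RapidChangeReport]]:
    """Full characterization of every component of a fitted decomposition."""
    partition = partition or result.partition
    if partition is None:
        raise ParameterError("a stage partition is required")
    vbar = stage_contributions(result.V, partition)
    stable = []
    rapid = []
    for r in range(result.p):
        U_r = result.stacked_states(r)
        stable.append(stable_connections(U_r, top_fraction, component=r))
        rapid.append(
            rapidly_changing_connections(U_r, vbar[:, r], top_fraction, component=r)
        )
    return stable, rapid
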