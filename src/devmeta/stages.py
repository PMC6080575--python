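"""Developmental stage identification by consensus k-means clustering.

The tau vectorized networks are treated as points in R^M and clustered many
times with randomized k-means seeding.  The consensus matrix records, for
each pair of time points, the fraction of runs in which they landed in the
same cluster; its dispersion coefficient

    rho(C) = (1 / tau^2) * sum_{i,j} 4 * (C_ij - 1/2)^2

is 1 exactly when every run produces the same partition and tends to 0 for
maximally unstable clusterings.  The stage count G is chosen as the largest
G attaining the maximal dispersion over a candidate range ("finest
granularity" rule): when several G are equally stable, the partition that
resolves the most developmental detail is preferred.

No temporal information enters the clustering itself; stages nevertheless
tend to come out as contiguous age blocks when the underlying networks
change smoothly, and a non-contiguous result is reported with a warning
rather than rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import ParameterError, ValidationError
from .networks import DevelopmentalNetworks

__all__ = [
    "ConsensusResult",
    "StagePartition",
    "consensus_cluster",
    "consensus_from_labels",
    "dispersion_coefficient",
    "select_stage_partition",
]

logger = logging.getLogger(__name__)

#: number of randomized clustering runs per candidate stage count
DEFAULT_N_RUNS = 100


@dataclass
class ConsensusResult:
    """Consensus clustering output for one candidate stage count."""

    n_clusters: int
    consensus: np.ndarray  # tau x tau co-clustering frequencies
    runs: list  # per-run label vectors, each of length tau
    dispersion: float
    inertias: list = field(default_factory=list)  # per-run k-means inertia


@dataclass
class StagePartition:
    """Assignment of the tau time points to G developmental stages.

    ``labels[i]`` is the 0-based stage index of time point i; stages are
    numbered chronologically by their earliest member.  ``blocks[t]`` holds
    the ordered time indices of stage t.
    """

    G: int
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.G)):
            raise ValidationError(
                f"labels must cover stages 0..{self.G - 1}, found {present.tolist()}"
            )

    @property
    def blocks(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == t) for t in range(self.G)]

    @property
    def sizes(self) -> list[int]:
        return [int(np.sum(self.labels == t)) for t in range(self.G)]

    @property
    def tau(self) -> int:
        return len(self.labels)

    def is_contiguous(self) -> bool:
        blocks = self.blocks
        return all(np.array_equal(b, np.arange(b[0], b[-1] + 1)) for b in blocks)


def _relabel_chronologically(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels so stage 0 contains the earliest time point."""
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    return np.asarray([order[lab] for lab in labels], dtype=int)


def consensus_from_labels(runs: list[np.ndarray]) -> np.ndarray:
    """Co-clustering frequency matrix from a list of label vectors."""
    runs = [np.asarray(r) for r in runs]
    tau = len(runs[0])
    consensus = np.zeros((tau, tau))
    for labels in runs:
        consensus += labels[:, None] == labels[None, :]
    consensus /= len(runs)
    return consensus


def consensus_cluster(
    X: DevelopmentalNetworks | np.ndarray,
    G: int,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int | None = None,
) -> ConsensusResult:
    """Run k-means ``n_runs`` times with randomized seeding and aggregate.

    Each run is one k-means (k-means++ randomized seeding, squared
    Euclidean distance) on the tau columns of X.  Deterministic given
    ``seed``.
    """
    data = X.X if isinstance(X, DevelopmentalNetworks) else np.asarray(X, dtype=float)
    tau = data.shape[1]
    if not 2 <= G <= tau:
        raise ParameterError(f"stage count G={G} must satisfy 2 <= G <= tau={tau}")
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    points = data.T  # tau samples of dimension M
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    runs: list[np.ndarray] = []
    inertias: list[float] = []
    for rs in run_seeds:
        km = KMeans(n_clusters=G, n_init=1, random_state=int(rs)).fit(points)
        runs.append(km.labels_.copy())
        inertias.append(float(km.inertia_))
    consensus = consensus_from_labels(runs)
    return ConsensusResult(
        n_clusters=G,
        consensus=consensus,
        runs=runs,
        dispersion=dispersion_coefficient(consensus),
        inertias=inertias,
    )


def dispersion_coefficient(consensus: np.ndarray) -> float:
    """rho = (1/tau^2) * sum 4*(C_ij - 1/2)^2, in [0, 1]; 1 = unanimous runs."""
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("consensus matrix must be square")
    if np.max(np.abs(C - C.T)) > 1e-12:
        raise ValidationError("consensus matrix must be symmetric")
    if C.min() < 0 or C.max() > 1:
        raise ValidationError("consensus entries must lie in [0, 1]")
    tau = C.shape[0]
    return float(np.sum(4.0 * (C - 0.5) ** 2) / tau**2)


def select_stage_partition(
    X: DevelopmentalNetworks | np.ndarray,
    G_range,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int | None = None,
) -> tuple[StagePartition, dict[int, float]]:
    """Choose the stage count with maximal dispersion at finest granularity.

    Runs :func:`consensus_cluster` for every G in ``G_range``; among the
    candidates attaining the maximal dispersion coefficient, the largest G
    wins.  The returned labels come from the best-inertia run at the
    selected G and are renumbered chronologically.
    """
    G_list = sorted(set(int(g) for g in G_range))
    if not G_list:
        raise ParameterError("G_range must be non-empty")
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = {g: int(s.generate_state(1)[0] % 2**31) for g, s in
                   zip(G_list, ss.spawn(len(G_list)))}
    results = {
        g: consensus_cluster(X, g, n_runs=n_runs, seed=child_seeds[g]) for g in G_list
    }
    curve = {g: results[g].dispersion for g in G_list}
    best = max(curve.values())
    # finest granularity: largest G among (near-exact) ties at the maximum
    selected = max(g for g, d in curve.items() if d >= best - 1e-12)
    res = results[selected]
    best_run = int(np.argmin(res.inertias))
    labels = _relabel_chronologically(res.runs[best_run])
    partition = StagePartition(G=selected, labels=labels)
    if not partition.is_contiguous():
        logger.warning(
            "selected stage partition is not contiguous in time: %s",
            partition.labels.tolist(),
        )
    return partition, curve
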