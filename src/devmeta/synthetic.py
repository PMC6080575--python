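"""Synthetic developmental networks with planted meta-network structure.

Two generators make every other module testable without any imaging data:

``generate_planted_networks``
    emits a sequence of tau vectorized networks built as stage-wise
    products U* V*^T plus non-negative noise.  The p planted components
    occupy disjoint edge supports (so their states are exactly orthogonal
    by construction), a fixed fraction of each support's edges is swapped
    at every stage transition (smooth drift of U), and the trajectories
    V* follow smooth, qualitatively distinct curves — decaying, rising,
    unimodal, flat — of the kind seen in developing structural networks.
    The ground truth is returned alongside the data for recovery tests.

``generate_thickness_tables``
    emits per-age subject x ROI cortical-thickness-like tables in which a
    small set of latent factors induces a target correlation structure,
    plus gender and whole-cortex scaling confounds, so the full
    table -> residual -> correlation-network path can be exercised.

Noise is additive Gaussian truncated at zero (negative draws clipped to
0), keeping the data in the model's non-negative domain; a half-normal
alternative (|N(0, sd)|) is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .networks import DevelopmentalNetworks, MeasurementTable
from .stages import StagePartition

__all__ = [
    "PlantedModel",
    "LatentThicknessModel",
    "generate_planted_networks",
    "generate_thickness_tables",
]

# Smooth trajectory shape library over normalized time t in [0, 1].  The
# amplitudes put the mean edge strength of the clean signal near 0.35 for
# the default support size, i.e. the default noise sd of 0.02 is a few
# percent of signal.
_CLASSIC_SHAPES = [
    lambda t: 1.6 * np.exp(-0.9 * t) + 0.8,  # decaying
    lambda t: 0.9 + 1.4 * t,  # rising
    lambda t: 1.2 + 1.2 * np.exp(-(((t - 0.5) / 0.22) ** 2)),  # unimodal
    lambda t: 1.8 * np.ones_like(t),  # flat
    lambda t: 2.2 - 1.2 * np.exp(-(((t - 0.5) / 0.25) ** 2)),  # u-shaped
    lambda t: 0.8 + 1.5 * t**2,  # late-rising
]


def _separated_trajectories(tgrid: np.ndarray, p: int) -> np.ndarray:
    """Maximally separable trajectory set: a regular simplex of deviations.

    Each trajectory is a shared positive baseline plus a deviation built
    from smooth cosine modes; the deviation vectors of the p trajectories
    form a regular simplex (all pairwise angles equal and maximal), so the
    minimal pairwise distance among the planted trajectories is as large
    as the smooth subspace allows.  Merging any subset strictly shrinks
    the minimal distance, which is what makes these trajectories suitable
    for component-number selection experiments.
    """
    c, g = 1.2, 0.8
    q = max(p - 1, 1)
    modes = np.column_stack(
        [np.sqrt(2.0) * np.cos((k + 1) * np.pi * tgrid) for k in range(q)]
    )
    # p unit vectors forming a regular simplex, expressed in q coordinates
    centered = np.eye(p) - 1.0 / p
    _, _, vt = np.linalg.svd(centered)
    coords = centered @ vt[:q].T  # p x q, rank q
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    V = c + g * modes @ coords.T
    return np.clip(V, 0.05, None)


_FAMILIES = ("classic", "separated")


@dataclass
class PlantedModel:
    """Ground truth emitted by :func:`generate_planted_networks`."""

    N: int
    tau: int
    p: int
    partition: StagePartition
    U_star: list  # G arrays (M, p), unit-norm columns on disjoint supports
    V_star: np.ndarray  # (tau, p) smooth non-negative trajectories
    supports: list  # per stage, list of p edge-index arrays
    noise_sd: float
    seed: int | None

    @property
    def M(self) -> int:
        return self.N * (self.N - 1) // 2

    @property
    def G(self) -> int:
        return self.partition.G

    def clean_X(self) -> np.ndarray:
        """Noiseless data: column i = U*^{stage(i)} V*(i, .)^T."""
        X = np.empty((self.M, self.tau))
        for i in range(self.tau):
            t = int(self.partition.labels[i])
            X[:, i] = self.U_star[t] @ self.V_star[i, :]
        return X

    @property
    def signal_level(self) -> float:
        """Mean of the nonzero entries of the clean data (edge-strength scale)."""
        clean = self.clean_X()
        nz = clean[clean > 0]
        return float(nz.mean()) if nz.size else 0.0


def _default_support_size(M: int, p: int) -> int:
    # sparse parts: each component covers ~5% of the edges
    return max(2, min(int(round(0.05 * M)), M // (2 * p)))


def generate_planted_networks(
    N: int = 40,
    tau: int = 12,
    G: int = 3,
    p: int = 3,
    drift: float = 0.1,
    noise_sd: float = 0.02,
    seed: int | None = 0,
    support_size: int | None = None,
    noise_kind: str = "truncated",
    trajectory_family: str = "classic",
) -> tuple[DevelopmentalNetworks, PlantedModel]:
    """Sequence of tau planted networks in G contiguous stage blocks.

    ``drift`` is the fraction of each component's support swapped for
    fresh edges at every stage transition; ``support_size`` defaults to
    about 5% of the M available edges per component.  The ``classic``
    trajectory family uses gentle decaying / rising / unimodal / flat
    curves of the kind observed in developing structural networks; the
    ``separated`` family plants a regular simplex of trajectory
    deviations — the maximally separable configuration used in
    component-number selection experiments.  Deterministic given
    ``seed``.
    """
    if G > tau:
        raise ParameterError(f"G={G} stages cannot partition tau={tau} time points")
    if noise_kind not in ("truncated", "half_normal"):
        raise ParameterError(f"unknown noise_kind {noise_kind!r}")
    if trajectory_family not in _FAMILIES:
        raise ParameterError(f"unknown trajectory_family {trajectory_family!r}")
    M = N * (N - 1) // 2
    s = support_size if support_size is not None else _default_support_size(M, p)
    if p * s > M:
        raise ParameterError(
            f"infeasible supports: {p} components x {s} edges exceed M={M}"
        )
    rng = np.random.default_rng(seed)
    labels = np.concatenate(
        [np.full(len(b), t) for t, b in enumerate(np.array_split(np.arange(tau), G))]
    )
    partition = StagePartition(G=G, labels=labels)

    # disjoint supports for stage 0, remaining edges form the free pool
    perm = rng.permutation(M)
    supports0 = [perm[r * s : (r + 1) * s].copy() for r in range(p)]
    free = list(perm[p * s :])
    weights0 = [rng.uniform(0.5, 1.5, size=s) for _ in range(p)]

    n_swap = int(round(drift * s))
    supports: list[list[np.ndarray]] = [supports0]
    weights: list[list[np.ndarray]] = [weights0]
    for _ in range(1, G):
        prev_sup = supports[-1]
        prev_w = weights[-1]
        cur_sup = []
        cur_w = []
        for r in range(p):
            sup = prev_sup[r].copy()
            w = prev_w[r].copy()
            if n_swap > 0:
                if len(free) < n_swap:
                    raise ParameterError(
                        "infeasible supports: free edge pool exhausted by drift"
                    )
                out_pos = rng.choice(s, size=n_swap, replace=False)
                incoming = [free.pop(rng.integers(len(free))) for _ in range(n_swap)]
                free.extend(sup[out_pos].tolist())
                sup[out_pos] = incoming
                w[out_pos] = rng.uniform(0.5, 1.5, size=n_swap)
            cur_sup.append(sup)
            cur_w.append(w)
        supports.append(cur_sup)
        weights.append(cur_w)

    U_star = []
    for t in range(G):
        Ut = np.zeros((M, p))
        for r in range(p):
            Ut[supports[t][r], r] = weights[t][r]
            Ut[:, r] /= np.linalg.norm(Ut[:, r])
        U_star.append(Ut)

    tgrid = np.linspace(0.0, 1.0, tau)
    if trajectory_family == "classic":
        V_star = np.column_stack(
            [_CLASSIC_SHAPES[r % len(_CLASSIC_SHAPES)](tgrid) for r in range(p)]
        )
    else:
        V_star = _separated_trajectories(tgrid, p)

    model = PlantedModel(
        N=N,
        tau=tau,
        p=p,
        partition=partition,
        U_star=U_star,
        V_star=V_star,
        supports=supports,
        noise_sd=noise_sd,
        seed=seed,
    )
    X = model.clean_X()
    if noise_sd > 0:
        g = rng.normal(0.0, noise_sd, size=X.shape)
        noise = np.maximum(g, 0.0) if noise_kind == "truncated" else np.abs(g)
        X = X + noise
    data = DevelopmentalNetworks(
        X=X,
        N=N,
        time_labels=list(range(3, 3 + tau)),
        node_names=[f"ROI{i:03d}" for i in range(N)],
    )
    return data, model


@dataclass
class LatentThicknessModel:
    """Latent-factor model behind the synthetic thickness tables.

    ROIs are split evenly across ``n_factors`` latent factors; two ROIs
    sharing a factor correlate with |r| ~ loading^2 / (loading^2 +
    noise_sd^2) after confound removal.  ``gender_effect`` shifts every
    ROI of one gender, and ``global_sd`` scales a per-subject whole-cortex
    factor — the two confounds the regression step is expected to remove.
    """

    n_factors: int = 4
    loading: float = 0.8
    noise_sd: float = 0.3
    gender_effect: float = 0.1
    global_sd: float = 0.15
    base_thickness: float = 2.5


def generate_thickness_tables(
    N: int = 78,
    tau: int = 18,
    subjects_per_age: int = 45,
    model: LatentThicknessModel | None = None,
    seed: int | None = 0,
    first_age: int = 3,
) -> list[MeasurementTable]:
    """Per-age subject x ROI tables with gender and mean-thickness confounds.

    Subject values are base thickness + per-subject global factor +
    factor loading * latent score + noise + gender offset.  Covariates
    carry ``gender`` (categorical) and ``mean_thickness`` (each subject's
    own cross-ROI mean).
    """
    if subjects_per_age < 4:
        raise ParameterError("need at least 4 subjects per age")
    model = model or LatentThicknessModel()
    rng = np.random.default_rng(seed)
    roi_names = [f"ROI{i:03d}" for i in range(N)]
    factor_of_roi = np.arange(N) % model.n_factors
    tables = []
    for age in range(first_age, first_age + tau):
        n = subjects_per_age
        scores = rng.normal(size=(n, model.n_factors))
        gender = rng.integers(0, 2, size=n)
        global_factor = rng.normal(0.0, model.global_sd, size=n)
        values = (
            model.base_thickness
            + global_factor[:, None]
            + model.loading * scores[:, factor_of_roi]
            + rng.normal(0.0, model.noise_sd, size=(n, N))
            + model.gender_effect * gender[:, None]
        )
        subjects = [f"sub-{age:02d}-{j:03d}" for j in range(n)]
        values_df = pd.DataFrame(values, index=subjects, columns=roi_names)
        covariates = pd.DataFrame(
            {
                "gender": np.where(gender == 0, "F", "M"),
                "mean_thickness": values.mean(axis=1),
            },
            index=subjects,
        )
        tables.append(
            MeasurementTable(
                timepoint_label=age, values=values_df, covariates=covariates
            )
        )
    return tables
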