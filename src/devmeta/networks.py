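"""Construction of cross-sectional structural correlation networks.

A structural correlation network summarises the covariance of a regional
morphometric measure (typically mean cortical thickness per ROI) across the
subjects scanned at one age: nodes are ROIs and the weight of edge (a, b) is
the absolute Pearson correlation of ROI a's and ROI b's thickness values
across subjects.  Before correlating, nuisance effects such as gender and a
subject's overall mean thickness are removed by per-ROI ordinary least
squares, and the residuals are correlated instead of the raw values.

The module provides the data containers for one measurement table, one
network, and the ordered stack of vectorized networks over all ages, plus
the operations that map tables -> networks -> stack.  Vectorization keeps
the strict upper triangle in row-major order, so an N-node network becomes a
vector of M = N(N-1)/2 connection strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateDesignError,
    InsufficientSampleError,
    ValidationError,
)

__all__ = [
    "MeasurementTable",
    "Network",
    "DevelopmentalNetworks",
    "regress_confounds",
    "build_correlation_network",
    "vectorize_network",
    "devectorize_network",
    "assemble_developmental_networks",
    "connection_labels",
]

#: maximum tolerated asymmetry max|A - A.T| before a matrix input is rejected
ASYMMETRY_TOL = 1e-8


@dataclass
class MeasurementTable:
    """Subject x ROI measurements at one time point, with subject covariates.

    Parameters
    ----------
    timepoint_label
        Ordinal age label (e.g., the integer age in years).
    values
        DataFrame of shape (subjects, ROIs); index identifies subjects,
        columns are ROI names in a fixed order shared across time points.
    covariates
        DataFrame indexed like ``values`` holding per-subject confounds
        (numeric or categorical).
    """

    timepoint_label: object
    values: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.covariates = pd.DataFrame(self.covariates)
        if self.values.isna().to_numpy().any():
            raise ValidationError(
                f"measurement table at {self.timepoint_label!r} contains missing values"
            )
        if not self.covariates.empty:
            if not self.covariates.index.equals(self.values.index):
                self.covariates = self.covariates.reindex(self.values.index)
                if self.covariates.isna().to_numpy().any():
                    raise ValidationError(
                        "covariates do not cover every subject in the measurement table"
                    )

    @property
    def roi_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)


@dataclass
class Network:
    """A symmetric non-negative weighted network over named nodes.

    ``weights`` is N x N with zero diagonal and entries in [0, 1] when
    produced by :func:`build_correlation_network` (absolute Pearson r).
    Matrix input that is asymmetric by more than ``ASYMMETRY_TOL`` is
    rejected; smaller asymmetries are symmetrized by averaging.
    """

    weights: np.ndarray
    node_names: list[str]
    timepoint_label: object = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"network weights must be square, got {w.shape}")
        if len(self.node_names) != w.shape[0]:
            raise ValidationError("node_names length does not match weight matrix")
        gap = np.max(np.abs(w - w.T)) if w.size else 0.0
        if gap > ASYMMETRY_TOL:
            raise ValidationError(
                f"weight matrix asymmetric: max|A - A^T| = {gap:.3g} > {ASYMMETRY_TOL:g}"
            )
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        if np.any(w < 0):
            raise ValidationError("network weights must be non-negative")
        self.weights = w
        self.node_names = list(self.node_names)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class DevelopmentalNetworks:
    """Ordered stack of vectorized networks: one column per time point.

    ``X`` has shape (M, tau) with M = N(N-1)/2 connections; column i is the
    upper-triangle vectorization of the network at ``time_labels[i]``.
    """

    X: np.ndarray
    N: int
    time_labels: list
    node_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValidationError("X must be a 2-D array of shape (M, tau)")
        expected_m = self.N * (self.N - 1) // 2
        if self.X.shape[0] != expected_m:
            raise ValidationError(
                f"X has {self.X.shape[0]} rows but N={self.N} implies M={expected_m}"
            )
        if self.X.shape[1] != len(self.time_labels):
            raise ValidationError("number of columns of X must equal len(time_labels)")
        if np.any(self.X < 0):
            raise ValidationError("developmental networks must be non-negative")
        self.time_labels = list(self.time_labels)

    @property
    def M(self) -> int:
        return self.X.shape[0]

    @property
    def tau(self) -> int:
        return self.X.shape[1]


def _design_matrix(
    covariates: pd.DataFrame, confound_names: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy-coded confound design; returns (matrix, column names)."""
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    for name in confound_names:
        if name not in covariates.columns:
            raise ConfigurationError(
                f"confound {name!r} not found among covariates "
                f"{list(covariates.columns)}"
            )
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            arr = col.to_numpy(dtype=float)
            if np.ptp(arr) == 0:
                # a constant covariate duplicates the intercept: no confound
                # information, so it is dropped and regression reduces to
                # mean removal
                continue
            cols.append(arr)
            names.append(name)
        else:
            # categorical: dummy coding with first level as reference
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dummy_name in dummies.columns:
                cols.append(dummies[dummy_name].to_numpy(dtype=float))
                names.append(dummy_name)
    design = np.column_stack(cols)
    # detect rank deficiency and name the offending confound
    rank = 1
    for j in range(1, design.shape[1]):
        new_rank = np.linalg.matrix_rank(design[:, : j + 1])
        if new_rank == rank:
            raise DegenerateDesignError(
                f"confound column {names[j]!r} is collinear with the preceding design"
            )
        rank = new_rank
    return design, names


def regress_confounds(
    table: MeasurementTable, confound_names: Sequence[str]
) -> MeasurementTable:
    """Remove confound effects from every ROI by ordinary least squares.

    For each ROI column, fits measurement ~ intercept + confounds and keeps
    the residuals.  Residuals have zero mean per ROI and zero Pearson
    correlation with every numeric confound (to numerical precision).
    Categorical confounds are dummy coded with the first level as reference.
    """
    design, _ = _design_matrix(table.covariates, confound_names)
    n, k = design.shape
    if n < k + 1:
        raise InsufficientSampleError(
            f"need at least {k + 1} subjects to regress {k - 1} confound columns, "
            f"got {n}"
        )
    y = table.values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ coef
    out = table.values.copy()
    out.loc[:, :] = residuals
    return MeasurementTable(
        timepoint_label=table.timepoint_label,
        values=out,
        covariates=table.covariates,
    )


def build_correlation_network(table: MeasurementTable) -> Network:
    """Absolute pairwise Pearson correlation of ROI columns across subjects.

    The diagonal (self-correlation) is set to zero.  Raises if any ROI has
    zero variance across subjects (correlation undefined) or if fewer than
    three subjects are available.
    """
    values = table.values.to_numpy(dtype=float)
    if values.shape[0] < 3:
        raise InsufficientSampleError(
            f"Pearson correlation requires >= 3 subjects, got {values.shape[0]}"
        )
    sd = values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        bad = [table.roi_names[i] for i in dead]
        raise ValidationError(f"zero-variance ROI(s): {bad}")
    corr = np.corrcoef(values, rowvar=False)
    weights = np.abs(corr)
    np.clip(weights, 0.0, 1.0, out=weights)
    np.fill_diagonal(weights, 0.0)
    weights = 0.5 * (weights + weights.T)
    return Network(
        weights=weights,
        node_names=table.roi_names,
        timepoint_label=table.timepoint_label,
    )


def vectorize_network(net: Network) -> np.ndarray:
    """Strict upper triangle of the weight matrix, row-major, length N(N-1)/2."""
    n = net.n_nodes
    iu = np.triu_indices(n, k=1)
    return net.weights[iu].copy()


def devectorize_network(
    vec: np.ndarray, node_names: Sequence[str], timepoint_label: object = None
) -> Network:
    """Inverse of :func:`vectorize_network`; exact round trip."""
    vec = np.asarray(vec, dtype=float)
    n = len(node_names)
    m = n * (n - 1) // 2
    if vec.shape != (m,):
        raise ValidationError(
            f"connection vector has length {vec.shape}, expected ({m},) for N={n}"
        )
    weights = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    weights[iu] = vec
    weights = weights + weights.T
    return Network(weights=weights, node_names=list(node_names), timepoint_label=timepoint_label)


def connection_labels(node_names: Sequence[str]) -> list[str]:
    """Edge labels 'a–b' in the same order as the vectorized upper triangle."""
    names = list(node_names)
    n = len(names)
    iu, ju = np.triu_indices(n, k=1)
    return [f"{names[i]}–{names[j]}" for i, j in zip(iu, ju)]


def assemble_developmental_networks(nets: Sequence[Network]) -> DevelopmentalNetworks:
    """Stack an ordered list of same-node networks into an (M, tau) matrix.

    Requires identical node sets/order across networks and strictly
    increasing time labels.
    """
    if not nets:
        raise ValidationError("need at least one network")
    ref = nets[0]
    for net in nets[1:]:
        if net.node_names != ref.node_names:
            diff = sorted(set(net.node_names) ^ set(ref.node_names))
            raise ValidationError(
                f"networks have mismatched node sets; symmetric difference: {diff}"
                if diff
                else "networks share node names but in different orders"
            )
    labels = [net.timepoint_label for net in nets]
    arr = np.asarray(labels, dtype=object)
    try:
        numeric = np.asarray(labels, dtype=float)
        increasing = bool(np.all(np.diff(numeric) > 0))
    except (TypeError, ValueError):
        increasing = all(a < b for a, b in zip(arr[:-1], arr[1:]))
    if len(labels) > 1 and not increasing:
        raise ValidationError(f"time labels must be strictly increasing, got {labels}")
    X = np.column_stack([vectorize_network(net) for net in nets])
    return DevelopmentalNetworks(
        X=X, N=ref.n_nodes, time_labels=labels, node_names=ref.node_names
    )
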