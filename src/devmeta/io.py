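"""Readers and writers for the package's on-disk formats.

Delimited text is the primary interchange format: measurement tables and
square network matrices are TSV with a header row, the vectorized stack is
a TSV with 'a–b' edge-row labels and time-label columns.  HDF5 mirrors the
stack and the fitted decomposition for fast round trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .dmd import DMDResult
from .errors import ConfigurationError
from .networks import (
    DevelopmentalNetworks,
    MeasurementTable,
    Network,
    connection_labels,
)
from .stages import StagePartition

__all__ = [
    "read_measurement_table",
    "write_network_tsv",
    "read_network_tsv",
    "write_stack_tsv",
    "read_stack_tsv",
    "write_stack_h5",
    "read_stack_h5",
    "write_result_h5",
    "read_result_h5",
    "write_partition_json",
    "read_partition_json",
    "load_config_file",
]


def read_measurement_table(
    measurements_path: str | Path,
    covariates_path: str | Path | None,
    timepoint_label,
    sep: str = "\t",
) -> MeasurementTable:
    """Load one subject x ROI table and its subject-keyed covariates."""
    values = pd.read_csv(measurements_path, sep=sep, index_col=0)
    covariates = (
        pd.read_csv(covariates_path, sep=sep, index_col=0)
        if covariates_path is not None
        else pd.DataFrame(index=values.index)
    )
    return MeasurementTable(
        timepoint_label=timepoint_label, values=values, covariates=covariates
    )


def write_network_tsv(net: Network, path: str | Path) -> None:
    pd.DataFrame(net.weights, index=net.node_names, columns=net.node_names).to_csv(
        path, sep="\t"
    )


def read_network_tsv(path: str | Path, timepoint_label=None) -> Network:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Network(
        weights=df.to_numpy(dtype=float),
        node_names=list(df.columns),
        timepoint_label=timepoint_label,
    )


def write_stack_tsv(stack: DevelopmentalNetworks, path: str | Path) -> None:
    labels = (
        connection_labels(stack.node_names)
        if stack.node_names is not None
        else [f"e{i}" for i in range(stack.M)]
    )
    pd.DataFrame(stack.X, index=labels, columns=stack.time_labels).to_csv(
        path, sep="\t"
    )


def read_stack_tsv(path: str | Path, N: int, node_names=None) -> DevelopmentalNetworks:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = []
    for c in df.columns:
        try:
            labels.append(int(c))
        except ValueError:
            labels.append(c)
    return DevelopmentalNetworks(
        X=df.to_numpy(dtype=float), N=N, time_labels=labels, node_names=node_names
    )


def write_stack_h5(stack: DevelopmentalNetworks, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=stack.X)
        f.attrs["N"] = stack.N
        f.create_dataset("time_labels", data=np.asarray(stack.time_labels, dtype=float))
        if stack.node_names is not None:
            f.create_dataset(
                "node_names", data=np.asarray(stack.node_names, dtype="S")
            )


def read_stack_h5(path: str | Path) -> DevelopmentalNetworks:
    with h5py.File(path, "r") as f:
        X = f["X"][()]
        N = int(f.attrs["N"])
        time_labels = f["time_labels"][()]
        labels = [int(t) if float(t).is_integer() else float(t) for t in time_labels]
        node_names = (
            [n.decode() for n in f["node_names"][()]] if "node_names" in f else None
        )
    return DevelopmentalNetworks(X=X, N=N, time_labels=labels, node_names=node_names)


def write_result_h5(result: DMDResult, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("U")
        for t, Ut in enumerate(result.U):
            g.create_dataset(f"stage_{t}", data=Ut)
        f.create_dataset("V", data=result.V)
        f.create_dataset("objective_trace", data=result.objective_trace)
        d = f.create_group("diagnostics")
        d.create_dataset("orthogonality_gap", data=np.asarray(result.orthogonality_gap))
        d.attrs["chosen_restart"] = result.chosen_restart
        d.attrs["final_objective"] = result.final_objective
        if result.partition is not None:
            f.create_dataset("stage_labels", data=result.partition.labels)


def read_result_h5(path: str | Path) -> DMDResult:
    with h5py.File(path, "r") as f:
        stages = sorted(f["U"], key=lambda s: int(s.split("_")[1]))
        U = [f["U"][s][()] for s in stages]
        V = f["V"][()]
        trace = f["objective_trace"][()]
        gaps = list(f["diagnostics"]["orthogonality_gap"][()])
        restart = int(f["diagnostics"].attrs["chosen_restart"])
        final = float(f["diagnostics"].attrs["final_objective"])
        partition = None
        if "stage_labels" in f:
            labels = f["stage_labels"][()]
            partition = StagePartition(G=len(U), labels=labels)
    return DMDResult(
        U=U,
        V=V,
        objective_trace=trace,
        orthogonality_gap=gaps,
        chosen_restart=restart,
        final_objective=final,
        partition=partition,
    )


def write_partition_json(
    partition: StagePartition, path: str | Path, dispersion_curve=None, extra=None
) -> None:
    payload = {
        "G": partition.G,
        "labels": partition.labels.tolist(),
        "blocks": [b.tolist() for b in partition.blocks],
        "sizes": partition.sizes,
    }
    if dispersion_curve is not None:
        payload["dispersion_curve"] = {str(k): v for k, v in dispersion_curve.items()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_partition_json(path: str | Path) -> StagePartition:
    payload = json.loads(Path(path).read_text())
    return StagePartition(G=int(payload["G"]), labels=np.asarray(payload["labels"]))


def load_config_file(path: str | Path) -> dict:
    """YAML or JSON config as a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise ConfigurationError(f"unsupported config format: {path.suffix!r}")
    if not isinstance(data, dict):
        raise ConfigurationError("config file must contain a mapping")
    return data
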