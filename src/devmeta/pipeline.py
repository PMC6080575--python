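"""End-to-end orchestration: networks -> stages -> model selection -> fit ->
characterization -> reproducibility, with a machine-readable run manifest.

A single top-level seed fans out to per-stage child seeds through a fixed
derivation rule (SeedSequence on [seed, stage index]), so any stage can be
re-run in isolation and reproduce its part of a full run bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .characterize import characterize_result, DEFAULT_TOP_FRACTION
from .dmd import DMDConfig, compute_mtd, fit, select_num_dms
from .errors import DevmetaError
from .networks import (
    assemble_developmental_networks,
    build_correlation_network,
    regress_confounds,
)
from .reproducibility import split_half_experiment
from .stages import DEFAULT_N_RUNS, select_stage_partition
from .synthetic import generate_planted_networks

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]

logger = logging.getLogger(__name__)

_STAGE_NAMES = ["networks", "stages", "select_p", "fit", "characterize", "reproduce"]


def derive_seed(seed: int | None, stage: str) -> int | None:
    """Deterministic per-stage child seed from the pipeline seed."""
    if seed is None:
        return None
    idx = _STAGE_NAMES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """Every knob of the pipeline; round-trips losslessly through YAML/JSON."""

    out_dir: str = "devmeta_run"
    # input: either a directory of measurement tables, a stack file, or synthetic
    measurements_dir: str | None = None
    covariates_file: str | None = None
    stack_file: str | None = None
    simulate: bool = True
    confounds: list = field(default_factory=lambda: ["gender", "mean_thickness"])
    g_min: int = 2
    g_max: int = 6
    p_min: int = 2
    p_max: int = 6
    p: int | None = None  # fixed p skips selection
    lam: float = 0.1
    alpha: float = 0.1
    beta: float = 0.1
    n_runs: int = DEFAULT_N_RUNS
    n_init: int = 100
    max_iter: int = 1000
    tol: float = 1e-6
    top_fraction: float = DEFAULT_TOP_FRACTION
    seed: int = 0
    log_level: str = "INFO"
    # synthetic-input parameters (used when simulate is true)
    sim_N: int = 40
    sim_tau: int = 12
    sim_G: int = 3
    sim_p: int = 3
    sim_drift: float = 0.1
    sim_noise_sd: float = 0.02

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls(**io.load_config_file(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_or_simulate(config: PipelineConfig, out: Path) -> tuple:
    if config.stack_file:
        return io.read_stack_h5(config.stack_file), None
    if config.measurements_dir:
        tables = []
        for path in sorted(Path(config.measurements_dir).glob("*.tsv")):
            label = int(path.stem.split("_")[-1])
            tables.append(
                io.read_measurement_table(path, config.covariates_file, label)
            )
        nets = []
        for table in sorted(tables, key=lambda t: t.timepoint_label):
            resid = regress_confounds(table, config.confounds)
            nets.append(build_correlation_network(resid))
        return assemble_developmental_networks(nets), None
    data, model = generate_planted_networks(
        N=config.sim_N,
        tau=config.sim_tau,
        G=config.sim_G,
        p=config.sim_p,
        drift=config.sim_drift,
        noise_sd=config.sim_noise_sd,
        seed=derive_seed(config.seed, "networks"),
    )
    return data, model


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the run manifest.

    Each stage writes its artifact before the next begins, so a failure
    leaves the completed artifacts on disk; the raised error names the
    failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": config.to_dict(),
        "seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in _STAGE_NAMES},
        "versions": {"numpy": np.__version__},
        "artifacts": {},
        "timings": {},
    }
    current = "networks"
    try:
        t0 = time.perf_counter()
        stack, model = _load_or_simulate(config, out)
        stack_path = out / "stack.h5"
        io.write_stack_h5(stack, stack_path)
        io.write_stack_tsv(stack, out / "stack.tsv")
        manifest["artifacts"]["networks"] = str(stack_path)
        manifest["timings"]["networks"] = time.perf_counter() - t0

        current = "stages"
        t0 = time.perf_counter()
        g_range = range(config.g_min, min(config.g_max, stack.tau) + 1)
        partition, curve = select_stage_partition(
            stack,
            g_range,
            n_runs=config.n_runs,
            seed=derive_seed(config.seed, "stages"),
        )
        stages_path = out / "stages.json"
        io.write_partition_json(partition, stages_path, dispersion_curve=curve)
        manifest["artifacts"]["stages"] = str(stages_path)
        manifest["timings"]["stages"] = time.perf_counter() - t0

        current = "select_p"
        t0 = time.perf_counter()
        base_cfg = DMDConfig(
            p=max(config.p or 2, 2),
            lam=config.lam,
            alpha=config.alpha,
            beta=config.beta,
            n_init=config.n_init,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=derive_seed(config.seed, "select_p"),
        )
        if config.p is None:
            p_star, mtd_curve, _ = select_num_dms(
                stack, partition, range(config.p_min, config.p_max + 1), base_cfg
            )
        else:
            p_star, mtd_curve = config.p, {}
        select_path = out / "mtd_curve.tsv"
        with open(select_path, "w") as fh:
            fh.write("p\tmtd\n")
            for p_val, mtd in sorted(mtd_curve.items()):
                fh.write(f"{p_val}\t{mtd:.8g}\n")
        manifest["artifacts"]["select_p"] = str(select_path)
        manifest["selected_p"] = p_star
        manifest["timings"]["select_p"] = time.perf_counter() - t0

        current = "fit"
        t0 = time.perf_counter()
        fit_cfg = dataclasses.replace(
            base_cfg, p=p_star, seed=derive_seed(config.seed, "fit")
        )
        result = fit(stack, partition, fit_cfg)
        result_path = out / "result.h5"
        io.write_result_h5(result, result_path)
        manifest["artifacts"]["fit"] = str(result_path)
        manifest["mtd"] = compute_mtd(result.V) if p_star >= 2 else None
        manifest["timings"]["fit"] = time.perf_counter() - t0

        current = "characterize"
        t0 = time.perf_counter()
        stable, rapid = characterize_result(
            result, partition, top_fraction=config.top_fraction
        )
        char_path = out / "characterization.json"
        char_payload = {
            "stable": [
                {
                    "component": rep.component,
                    "threshold": rep.threshold,
                    "selected_edges": rep.selected.tolist(),
                }
                for rep in stable
            ],
            "rapid": [
                {
                    "component": rep.component,
                    "delta_vbar": rep.delta_vbar.tolist(),
                    "increased": {str(t): v.tolist() for t, v in rep.increased.items()},
                    "decreased": {str(t): v.tolist() for t, v in rep.decreased.items()},
                }
                for rep in rapid
            ],
        }
        char_path.write_text(json.dumps(char_payload, indent=2))
        manifest["artifacts"]["characterize"] = str(char_path)
        manifest["timings"]["characterize"] = time.perf_counter() - t0

        current = "reproduce"
        t0 = time.perf_counter()
        repro_cfg = dataclasses.replace(
            fit_cfg, seed=derive_seed(config.seed, "reproduce")
        )
        mean_u, mean_v, table = split_half_experiment(stack, partition, repro_cfg)
        repro_path = out / "reproducibility.json"
        repro_path.write_text(
            json.dumps(
                {
                    "mean_u_cosine": mean_u,
                    "mean_v_cosine": mean_v,
                    "per_component": table.to_dict(orient="records"),
                },
                indent=2,
                default=float,
            )
        )
        manifest["artifacts"]["reproduce"] = str(repro_path)
        manifest["timings"]["reproduce"] = time.perf_counter() - t0
    except Exception as exc:
        manifest["failed_stage"] = current
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise DevmetaError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
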