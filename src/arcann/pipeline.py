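"""End-to-end pipeline: generate, prepare, screen, select, compare, simulate.

``run_pipeline`` executes the whole model-development protocol on
synthetic data and returns (and optionally writes) its artifacts: the
two tables, per-output leaderboards, the chosen network per population,
total-abundance fits by summation, an SMLR baseline comparison, and
simulation grids for the chosen models.

Two scale presets are provided.  ``ci`` is a reduced screen (two input
combinations per output, 2 or 4 hidden units, 5 phase-1 / 10 phase-2
restarts, 30 LM iterations) sized for routine test runs; ``full`` is
the full protocol (all 25 subsets, 2-15 units, 100/1000 restarts, 100
iterations).  All randomness flows from the single master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model_search as ms
from .data_prep import log_policy
from .io import write_env_table
from .networks import network_to_json
from .simulate import (
    SEASONAL_RANGES,
    VIRAL_SIM_DEPTHS,
    Axis,
    simulate_grid,
    total_grid,
)
from .stats import linfit, smlr
from .synthetic_data import (
    ABUNDANCE_COLUMNS,
    COVARIATE_COLUMNS,
    GeneratorConfig,
    generate_seasonal,
    generate_spatial,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "CI_SUBSETS"]

#: Reduced-scale input combinations per output: the generator's true
#: predictors plus a decoy subset.
CI_SUBSETS = {
    "hna": [("chl_a_ug_l", "temperature_c"), ("salinity_psu",)],
    "lna": [("chl_a_ug_l", "temperature_c"), ("salinity_psu",)],
    "v1": [("chl_a_ug_l", "day_length_h", "depth_m"), ("salinity_psu", "temperature_c")],
    "v2": [("chl_a_ug_l", "day_length_h", "depth_m"), ("salinity_psu", "temperature_c")],
}


@dataclass
class PipelineConfig:
    master_seed: int = 0
    scale: str = "ci"  # "ci" | "full"
    outputs: tuple = ("hna", "lna", "v1", "v2")
    generator: GeneratorConfig | None = None
    subsets: dict | None = None  # per-output input combinations, None = preset
    hidden_counts: tuple | None = None
    restarts_phase1: int | None = None
    restarts_phase2: int | None = None
    max_iter: int | None = None
    shortlist_size: int = 4
    grid_points: int | None = None
    out_dir: str | None = None

    def resolved(self) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        if cfg.scale not in ("ci", "full"):
            raise ValueError(f"unknown scale preset {cfg.scale!r}")
        ci = cfg.scale == "ci"
        if cfg.generator is None:
            cfg.generator = GeneratorConfig(seed=cfg.master_seed)
        if cfg.subsets is None:
            cfg.subsets = CI_SUBSETS if ci else {o: None for o in cfg.outputs}
        if cfg.hidden_counts is None:
            cfg.hidden_counts = (2, 4) if ci else tuple(range(2, 16))
        if cfg.restarts_phase1 is None:
            cfg.restarts_phase1 = 5 if ci else 100
        if cfg.restarts_phase2 is None:
            cfg.restarts_phase2 = 10 if ci else 1000
        if cfg.max_iter is None:
            cfg.max_iter = 30 if ci else 100
        if cfg.grid_points is None:
            cfg.grid_points = 15 if ci else 50
        return cfg

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        payload = plain(dataclasses.asdict(self))
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if payload.get("generator") is not None:
            payload["generator"] = GeneratorConfig(**payload["generator"])
        if payload.get("subsets") is not None:
            payload["subsets"] = {
                k: None if v is None else [tuple(s) for s in v]
                for k, v in payload["subsets"].items()
            }
        payload["outputs"] = tuple(payload["outputs"])
        if payload.get("hidden_counts") is not None:
            payload["hidden_counts"] = tuple(payload["hidden_counts"])
        return cls(**payload)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self.resolved())
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    seasonal: pd.DataFrame
    spatial: pd.DataFrame
    data: ms.ModelingData
    leaderboards: dict  # output -> DataFrame
    chosen: dict  # output -> CandidateResult | None
    totals: dict  # "prokaryotes"/"viruses" -> {"seasonal": fit, "spatial": fit}
    smlr_models: dict  # output -> SMLRModel
    grids: dict  # output (+ totals) -> SimulationGrid
    report: dict


def _candidate_specs(cfg: PipelineConfig, output: str):
    subsets = cfg.subsets.get(output)
    hr = (min(cfg.hidden_counts), max(cfg.hidden_counts))
    specs = ms.enumerate_candidates(output, subsets=subsets, hidden_range=hr)
    return [s for s in specs if s.n_hidden in cfg.hidden_counts]


def _smlr_baseline(output: str, data: ms.ModelingData):
    """SMLR on log-policy-transformed seasonal data, evaluated on the
    spatial survey by observed-vs-predicted squared correlation in
    abundance units (the same scale the network models are judged on)."""
    ycol = ABUNDANCE_COLUMNS[output]
    seasonal = log_policy(data.seasonal)
    spatial = log_policy(data.spatial)
    model = smlr(seasonal[ycol].to_numpy(), seasonal[COVARIATE_COLUMNS])
    pred = np.exp(model.predict(spatial))  # back to abundance units
    obs = data.spatial[ycol].to_numpy(float)
    if np.std(pred) == 0:
        model.r2_eval = 0.0
    else:
        model.r2_eval = float(np.corrcoef(pred, obs)[0, 1] ** 2)
    return model


def _simulation_axes(result: ms.CandidateResult, n_points: int):
    """Grid axes over the model's own inputs; depth enters as the five
    fixed slices, other covariates as linspace over the seasonal range."""
    axes, depth_slices = [], None
    for col in result.spec.inputs:
        if col == "depth_m":
            depth_slices = VIRAL_SIM_DEPTHS
        else:
            lo, hi = SEASONAL_RANGES[col]
            axes.append(Axis.linspace(col, lo, hi, n_points))
    return axes, depth_slices


def _simulate_chosen(result: ms.CandidateResult, data: ms.ModelingData,
                     n_points: int):
    axes, depth_slices = _simulation_axes(result, n_points)
    if depth_slices is None:
        return simulate_grid(result, axes, data.scaler)
    grids = [
        simulate_grid(result, axes, data.scaler, fixed={"depth_m": z})
        for z in depth_slices
    ]
    # stack the depth slices as a leading fixed axis
    stacked = np.stack([g.values for g in grids])
    extrap = np.stack([g.extrapolation for g in grids])
    from .simulate import SimulationGrid

    return SimulationGrid(
        axes=[Axis.fixed("depth_m", depth_slices), *axes],
        values=stacked,
        model_id=result.spec.spec_id,
        extrapolation=extrap,
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    cfg = cfg.resolved()
    seasonal = generate_seasonal(cfg.generator)
    spatial = generate_spatial(cfg.generator)
    data = ms.prepare_modeling_data(seasonal, spatial, split_seed=cfg.master_seed)

    leaderboards, chosen, smlr_models, grids = {}, {}, {}, {}
    for output in cfg.outputs:
        specs = _candidate_specs(cfg, output)
        p1 = ms.phase1(specs, data, cfg.restarts_phase1, cfg.master_seed,
                       cfg.max_iter)
        p1.sort(key=lambda r: r.combined_rmse)
        shortlist = [r.spec for r in p1[: cfg.shortlist_size]]
        p2 = ms.phase2(shortlist, data, cfg.restarts_phase2, cfg.master_seed,
                       cfg.max_iter)
        leaderboards[output] = ms.leaderboard(p2)
        try:
            best = ms.select_best(p2)
        except ms.NoAdmissibleModelError:
            best = None
        chosen[output] = best
        smlr_models[output] = _smlr_baseline(output, data)
        if best is not None:
            grids[output] = _simulate_chosen(best, data, cfg.grid_points)

    totals = {}
    for total_col, (a, b) in (
        ("prokaryotes_1e5_ml", ("hna", "lna")),
        ("viruses_1e6_ml", ("v1", "v2")),
    ):
        if chosen.get(a) is None or chosen.get(b) is None:
            continue
        entry = {}
        for tag, table in (("seasonal", seasonal), ("spatial", spatial)):
            summed = ms.total_abundance(
                ms.predict_abundance(chosen[a], table, data.scaler),
                ms.predict_abundance(chosen[b], table, data.scaler),
            )
            entry[tag] = linfit(summed, table[total_col].to_numpy(float))
        totals[total_col] = entry
        if a in grids and b in grids:
            try:
                grids[total_col] = total_grid(grids[a], grids[b])
            except ValueError:
                pass  # component models on different input subsets

    report = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "scale": cfg.scale,
        "chosen": {
            o: None
            if chosen[o] is None
            else {
                "inputs": list(chosen[o].spec.inputs),
                "type": chosen[o].spec.net_type,
                "units": chosen[o].spec.n_hidden,
                "rmse": chosen[o].combined_rmse,
                "r2_spatial": chosen[o].spatial_fit.r2,
                "k_spatial": chosen[o].spatial_fit.slope,
            }
            for o in cfg.outputs
        },
        "totals": {
            k: {tag: {"r2": f.r2, "intercept": f.intercept, "k": f.slope}
                for tag, f in v.items()}
            for k, v in totals.items()
        },
        "smlr": {
            o: {
                "predictors": m.predictors,
                "r2": m.r2,
                "r2_spatial": m.r2_eval,
            }
            for o, m in smlr_models.items()
        },
    }
    result = PipelineResult(cfg, seasonal, spatial, data, leaderboards, chosen,
                            totals, smlr_models, grids, report)
    if cfg.out_dir is not None:
        _write_artifacts(result)
    return result


def _write_artifacts(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_env_table(result.seasonal, out / "seasonal.csv")
    write_env_table(result.spatial, out / "spatial.csv")
    for o, lb in result.leaderboards.items():
        lb.to_csv(out / f"leaderboard_{o}.csv", index=False)
    for o, best in result.chosen.items():
        if best is not None:
            (out / f"model_{o}.json").write_text(
                network_to_json(best.network(), best.spec)
            )
    (out / "scaler.json").write_text(result.data.scaler.to_json())
    for name, grid in result.grids.items():
        grid.to_frame().to_csv(out / f"grid_{name}.csv", index=False)
    (out / "report.json").write_text(json.dumps(result.report, indent=2))
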