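"""Experiment registry: the scripted simulation batteries.

Each experiment runs one named condition set over a block of seeds,
writes one trace file per run (CSV) and a summary table (per-run metrics
plus median/IQR aggregates) into the output directory, and returns the
per-run summary frame.  Everything is deterministic given
(config, base_seed): run i of condition c uses the generator seeded with
(base_seed, c, i).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AgentConfig
from .metrics import (
    aggregate,
    occlusion_run_summary,
    timesharing_run_summary,
)
from .occlusion import (
    OcclusionConfig,
    epistemic_saliency_map,
    run_occlusion_simulation,
)
from .timesharing import TimesharingConfig, run_timesharing_simulation, value_curves

__all__ = ["EXPERIMENTS", "run_experiment", "load_config"]

#: default sweep grids (the published figures do not print theirs)
PREF_SWEEP_GAZE = (-5.0, -7.0, -10.0)
PREF_SWEEP_SPEED_SIGMA = (0.5, 2.0)
VALUE_CURVE_PREFS = (-7.0, -10.0)
VALUE_CURVE_GRID = np.round(np.geomspace(0.01, 2.0, 40), 6)
SALIENCY_X_GRID = np.arange(0.0, 40.1, 2.0)
SALIENCY_Y_GRID = np.arange(-1.5, 1.51, 0.5)


def load_config(path) -> dict:
    """Read a YAML run-configuration file (sections: scenario, planner,
    filter, experiment)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must contain a mapping")
    return cfg


def _build(cls, overrides: dict | None, section: str):
    overrides = dict(overrides or {})
    valid = {f.name for f in dataclasses.fields(cls)}
    bad = set(overrides) - valid
    if bad:
        raise ValueError(f"unknown key(s) in config section '{section}': {sorted(bad)}")
    return cls(**overrides)


def _agent_from_config(config: dict, profile: str) -> AgentConfig:
    agent = AgentConfig.from_profile(profile)
    overrides = {**(config.get("filter") or {}), **(config.get("planner") or {})}
    valid = {f.name for f in dataclasses.fields(AgentConfig)}
    bad = set(overrides) - valid
    if bad:
        raise ValueError(f"unknown key(s) in config sections 'filter'/'planner': {sorted(bad)}")
    return agent.with_overrides(**overrides)


def _seed_for(base_seed: int, condition: int, run: int):
    return [int(base_seed), int(condition), int(run)]


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _occlusion_battery(variant):
    def runner(config, agent, n_seeds, out_dir, base_seed):
        scen = _build(OcclusionConfig, config.get("scenario"), "scenario")
        rows = []
        for i in range(n_seeds):
            seed = _seed_for(base_seed, 0, i)
            trace = run_occlusion_simulation(scen, agent, variant, seed)
            _write(trace, out_dir / f"trace_sim{variant}_run{i}.csv")
            summary = occlusion_run_summary(trace)
            summary["conflict_count"] = int(np.asarray(trace["conflict"]).sum())
            rows.append({"variant": variant, "seed": i, **summary})
        return pd.DataFrame(rows), None
    return runner


def _sim2a(config, agent, n_seeds, out_dir, base_seed):
    scen = _build(TimesharingConfig, config.get("scenario"), "scenario")
    rows = []
    for c, (label, pref) in enumerate([("baseline", 0.0), ("vts", -7.0)]):
        cond = dataclasses.replace(scen, log_p_on=pref)
        for i in range(n_seeds):
            trace = run_timesharing_simulation(cond, agent, _seed_for(base_seed, c, i))
            _write(trace, out_dir / f"trace_sim2a_{label}_run{i}.csv")
            rows.append({"condition": label, "gaze_pref": pref, "seed": i,
                         **timesharing_run_summary(trace)})
    return pd.DataFrame(rows), ["condition"]


def _sim2b(config, agent, n_seeds, out_dir, base_seed):
    scen = _build(TimesharingConfig, config.get("scenario"), "scenario")
    rows = []
    for c, (label, width) in enumerate([("wide", 3.0), ("narrow", 2.5)]):
        cond = dataclasses.replace(scen, lane_width=width, log_p_on=-7.0)
        for i in range(n_seeds):
            trace = run_timesharing_simulation(cond, agent, _seed_for(base_seed, c, i))
            _write(trace, out_dir / f"trace_sim2b_{label}_run{i}.csv")
            rows.append({"condition": label, "lane_width": width, "seed": i,
                         **timesharing_run_summary(trace)})
    return pd.DataFrame(rows), ["condition"]


def _pref_sweep(config, agent, n_seeds, out_dir, base_seed):
    scen = _build(TimesharingConfig, config.get("scenario"), "scenario")
    rows = []
    c = 0
    for speed_sigma in PREF_SWEEP_SPEED_SIGMA:
        for gaze in PREF_SWEEP_GAZE:
            cond = dataclasses.replace(scen, log_p_on=gaze, speed_sigma=speed_sigma)
            for i in range(n_seeds):
                trace = run_timesharing_simulation(cond, agent, _seed_for(base_seed, c, i))
                _write(
                    trace,
                    out_dir / f"trace_sweep_g{gaze:g}_s{speed_sigma:g}_run{i}.csv",
                )
                rows.append({
                    "gaze_pref": gaze, "speed_sigma": speed_sigma, "seed": i,
                    **timesharing_run_summary(trace),
                })
            c += 1
    return pd.DataFrame(rows), ["speed_sigma", "gaze_pref"]


def _saliency(config, agent, n_seeds, out_dir, base_seed):
    scen = _build(OcclusionConfig, config.get("scenario"), "scenario")
    rows = []
    for label, p in [("belief20", 0.2), ("belief0", 0.0)]:
        grid = epistemic_saliency_map(SALIENCY_Y_GRID, SALIENCY_X_GRID, p, scen, agent)
        df = pd.DataFrame(grid, index=SALIENCY_Y_GRID, columns=SALIENCY_X_GRID)
        df.index.name = "y"
        df.to_csv(out_dir / f"saliency_{label}.csv")
        for i, y in enumerate(SALIENCY_Y_GRID):
            for j, x in enumerate(SALIENCY_X_GRID):
                rows.append({"belief": p, "x": float(x), "y": float(y),
                             "epistemic": float(grid[i, j])})
    return pd.DataFrame(rows), None


def _value_curves(config, agent, n_seeds, out_dir, base_seed):
    scen = _build(TimesharingConfig, config.get("scenario"), "scenario")
    rows = []
    for pref in VALUE_CURVE_PREFS:
        table, sigma_star = value_curves(
            VALUE_CURVE_GRID, pref, scen, agent, seed=int(base_seed)
        )
        _write(table, out_dir / f"value_curves_pref{pref:g}.csv")
        rows.append({
            "gaze_pref": pref,
            "sigma_star": np.nan if sigma_star is None else sigma_star,
        })
    return pd.DataFrame(rows), None


EXPERIMENTS = {
    "sim1a": _occlusion_battery("1a"),
    "sim1b": _occlusion_battery("1b"),
    "sim1c": _occlusion_battery("1c"),
    "sim1d": _occlusion_battery("1d"),
    "saliency": _saliency,
    "sim2a": _sim2a,
    "sim2b": _sim2b,
    "value_curves": _value_curves,
    "pref_sweep": _pref_sweep,
}


def run_experiment(
    name: str,
    config: dict | str | Path | None = None,
    n_seeds: int = 10,
    out_dir: str | Path = "results",
    base_seed: int = 0,
    profile: str = "default",
) -> pd.DataFrame:
    """Run a named experiment battery and write traces + summary.

    ``config`` may be a YAML path or an already-loaded mapping; ``profile``
    selects the agent hyperparameter profile ('default' or 'test').
    Returns the per-run summary DataFrame (also written, with median/IQR
    aggregate rows appended, to ``<out_dir>/summary_<name>.csv``).
    """
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; expected one of {sorted(EXPERIMENTS)}")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if isinstance(config, (str, Path)):
        config = load_config(config)
    config = config or {}
    agent = _agent_from_config(config, profile)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_run, group_cols = EXPERIMENTS[name](config, agent, n_seeds, out_dir, base_seed)
    _write(per_run, out_dir / f"summary_{name}.csv")
    if "seed" in per_run.columns:
        agg = aggregate(per_run, by=group_cols)
        _write(agg, out_dir / f"summary_{name}_aggregate.csv")
    return per_run
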