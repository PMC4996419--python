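"""Config-driven scenarios tying the analysis stages together.

A scenario config is a flat YAML/JSON mapping with at least ``scenario`` and
``seed``; everything else is scenario-specific.  Every run writes its
outputs plus a manifest (config echo, derived seeds, package versions, wall
time) into a fresh directory, so any scenario is re-runnable from its
manifest alone.  The single top-level seed fans out to per-stage seeds by
stable hashing of the stage name, so stages stay independently reproducible
when a config grows.
"""

from __future__ import annotations

import datetime
import json
import shutil
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import design_regime_conditions
from .dynamics import DEFAULT_T_DAY, fate_grid
from .equilibria import bifurcation_scan
from .errors import CrossfeedError, ScenarioError
from .estimation import classify_experimental_regime, split_tracks
from .experiment import ExperimentConfig, read_plate, simulate_plate, write_plate
from .gillespie import StochasticConfig, ensemble_stats
from .invasion import FourStrainParams, invasion_scan
from .model import ModelParams
from .regimes import EFFECT_LEGEND, regime_map_2d

__all__ = ["run_scenario", "SCENARIOS", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2**31)


def _params_from(config: dict) -> ModelParams:
    return ModelParams.from_dict(config.get("params", {}))


def _scenario_bifurcation_scan(config, outdir, seed):
    a = np.arange(config.get("a_min", 0.01), config.get("a_max", 1.0) + 1e-12,
                  config.get("step", 0.01))
    diagram = bifurcation_scan(_params_from(config), a)
    diagram.to_csv(outdir / "bifurcation.csv")
    (outdir / "boundaries.json").write_text(
        json.dumps(diagram.boundary_summary(), indent=2) + "\n"
    )
    return {"n_grid": int(a.size), "boundaries": diagram.boundary_summary()}


def _scenario_regime_map(config, outdir, seed):
    a = np.arange(config.get("a_min", 0.01), config.get("a_max", 1.0) + 1e-12,
                  config.get("step", 0.01))
    axis_name = config.get("axis", "c")
    axis_grid = np.asarray(config.get("axis_grid", [0.5, 0.75, 1.0]), float)
    rmap = regime_map_2d(_params_from(config), a, axis_name, axis_grid,
                         rel_tol=config.get("rel_tol", 0.0))
    rmap.to_csv(outdir / "regime_map.csv")
    (outdir / "legend.json").write_text(json.dumps(EFFECT_LEGEND, indent=2) + "\n")
    return {"cells": int(a.size * axis_grid.size)}


def _scenario_fate_grid(config, outdir, seed):
    params = _params_from(config)
    grid = fate_grid(
        params,
        np.asarray(config.get("n_values", np.geomspace(1e-3, 0.5, 8)), float),
        np.asarray(config.get("f_values", np.geomspace(0.1, 10, 8)), float),
        t_end=config.get("t_end", 500.0),
    )
    grid.to_csv(outdir / "fate_grid.csv", index=False)
    return {"cells": int(len(grid))}


def _scenario_gillespie_ensemble(config, outdir, seed):
    params = _params_from(config)
    scfg = StochasticConfig(
        omega=config.get("omega", 10_000),
        seed=stage_seed(seed, "gillespie"),
        t_max=config.get("t_max", 50.0),
        record_dt=config.get("record_dt", 0.5),
    )
    x0 = config.get("initial_counts")
    if x0 is None:
        x0 = (scfg.omega // 5, scfg.omega // 5)
    stats = ensemble_stats(params, scfg, x0, config.get("n_replicates", 10))
    (outdir / "ensemble.json").write_text(json.dumps(stats.to_dict()) + "\n")
    pd.DataFrame(
        {"t": stats.t, "mean_X": stats.mean_X, "mean_Y": stats.mean_Y,
         "var_n": stats.var_n, "var_f": stats.var_f}
    ).to_csv(outdir / "ensemble_mean.csv", index=False)
    return {"n_replicates": stats.n_replicates,
            "extinction_fraction": stats.extinction_fraction}


def _scenario_invasion_scan(config, outdir, seed):
    fp = FourStrainParams(
        base=_params_from(config),
        r_d=config.get("r_d", 0.6),
        r_n=config.get("r_n", 1.05),
        w=config.get("w", 1.0),
        w_beta=config.get("w_beta", 1.0),
    )
    a = np.geomspace(config.get("a_min", 0.01), config.get("a_max", 5.0),
                     config.get("n_points", 20))
    scan = invasion_scan(fp, a, t_end=config.get("t_end", 2000.0))
    scan.to_csv(outdir / "invasion.csv")
    (outdir / "zones.json").write_text(
        json.dumps({"a": scan.a_grid.tolist(), "zone": scan.zones}, indent=2) + "\n"
    )
    return {"zones": sorted(set(scan.zones))}


def _experiment_config_from(config, seed) -> ExperimentConfig:
    kw = dict(config.get("experiment", {}))
    kw.setdefault("seed", stage_seed(seed, "plate"))
    if "conditions" in kw:
        kw["conditions"] = tuple(kw["conditions"])
    if "co_initial" in kw:
        kw["co_initial"] = tuple(tuple(x) for x in kw["co_initial"])
    return ExperimentConfig(**kw)


def _scenario_synthetic_plate(config, outdir, seed):
    ecfg = _experiment_config_from(config, seed)
    plate = simulate_plate(ecfg, _params_from(config))
    write_plate(plate, outdir / "plate.csv", ecfg)
    return {"records": int(len(plate))}


def _analyze(plate, rel_tol, seed):
    rows = []
    for trp in sorted(plate["trp_uM"].astype(float).unique()):
        mono_x, mono_y, cos = split_tracks(plate, trp)
        if len(mono_x) == 0 or len(mono_y) == 0 or not cos:
            continue
        label = classify_experimental_regime(
            mono_x, mono_y, cos, rel_tol=rel_tol,
            seed=stage_seed(seed, f"analyze:{trp}"),
        )
        rows.append(
            {"trp_uM": trp, "label": label.name,
             "effect_x": label.effect_x, "effect_y": label.effect_y}
        )
    return pd.DataFrame(rows)


def _scenario_analyze_plate(config, outdir, seed):
    plate = read_plate(config["plate"])
    results = _analyze(plate, config.get("rel_tol", 0.05), seed)
    results.to_csv(outdir / "regime_calls.csv", index=False)
    return {"conditions": int(len(results))}


def _scenario_end_to_end(config, outdir, seed):
    """Generate noise-free plates for designed conditions, analyze them, and
    compare pipeline calls against the daily-map ground truth."""
    params = _params_from(config)
    rel_tol = config.get("rel_tol", 0.05)
    t_day = config.get("t_day", DEFAULT_T_DAY)
    dilution = config.get("dilution_factor", 10.0)
    designs = design_regime_conditions(params, dilution, t_day, rel_tol=rel_tol)
    scale = config.get("concentration_scale", 0.1)
    rows = []
    for d in designs:
        # wells are seeded with the POST-dilution state so the first
        # end-of-day measurement already sits on the daily-map equilibrium
        if d.label.name == "competitive_exclusion":
            co_initial = tuple((0.3, fy) for fy in (0.2, 0.35, 0.5, 0.65, 0.8))
        elif d.co_equilibrium.n > 1e-6:
            st = d.co_equilibrium
            co_initial = ((st.n / dilution, st.Y / st.n),)
        else:
            co_initial = ((0.1, 0.5),)
        mono_initial = (d.x_mono / dilution if d.x_mono > 1e-6 else 0.05,
                        d.y_mono / dilution if d.y_mono > 1e-6 else 0.05)
        ecfg = ExperimentConfig(
            conditions=(d.a / scale,), co_initial=co_initial,
            mono_initial=mono_initial,
            od_noise_sd=0.0, cytometer_sample=None, t_day=t_day,
            concentration_scale=scale, seed=stage_seed(seed, f"e2e:{d.a:.6f}"),
        )
        plate = simulate_plate(ecfg, params)
        mono_x, mono_y, cos = split_tracks(plate, d.a / scale)
        called = classify_experimental_regime(mono_x, mono_y, cos, rel_tol=rel_tol)
        rows.append(
            {"a": d.a, "trp_uM": d.a / scale, "truth": d.label.name,
             "called": called.name, "agree": called.name == d.label.name}
        )
    results = pd.DataFrame(rows)
    results.to_csv(outdir / "end_to_end.csv", index=False)
    return {
        "conditions": int(len(results)),
        "agreement": int(results["agree"].sum()),
    }


SCENARIOS = {
    "bifurcation_scan": _scenario_bifurcation_scan,
    "regime_map": _scenario_regime_map,
    "fate_grid": _scenario_fate_grid,
    "gillespie_ensemble": _scenario_gillespie_ensemble,
    "invasion_scan": _scenario_invasion_scan,
    "synthetic_plate": _scenario_synthetic_plate,
    "analyze_plate": _scenario_analyze_plate,
    "end_to_end": _scenario_end_to_end,
}


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ScenarioError(f"{path}: config must be a mapping")
    return data


def run_scenario(config, out_root=None) -> Path:
    """Run one scenario and return its artifact directory.

    ``config`` is a mapping or a path to a YAML/JSON file.  On any error the
    partially written directory is removed before the error propagates.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    name = config.get("scenario")
    if name not in SCENARIOS:
        raise ScenarioError(
            f"unknown scenario {name!r}; choose one of {sorted(SCENARIOS)}"
        )
    seed = int(config.get("seed", 0))
    out_root = Path(out_root or config.get("out_root", "runs"))
    stamp = datetime.datetime.now().strftime("%Y%m%dT%H%M%S")
    outdir = out_root / f"{name}-{stamp}-{stage_seed(seed, name):08d}"
    i = 0
    while outdir.exists():
        i += 1
        outdir = out_root / f"{name}-{stamp}-{stage_seed(seed, name):08d}.{i}"
    outdir.mkdir(parents=True)
    t0 = time.perf_counter()
    try:
        summary = SCENARIOS[name](config, outdir, seed)
    except Exception:
        shutil.rmtree(outdir, ignore_errors=True)
        raise
    manifest = {
        "scenario": name,
        "seed": seed,
        "config": _jsonable(config),
        "versions": _versions(),
        "wall_time_s": round(time.perf_counter() - t0, 3),
        "summary": _jsonable(summary),
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def _versions() -> dict:
    import numpy
    import pandas
    import scipy

    return {
        "crossfeed": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
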