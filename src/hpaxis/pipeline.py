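"""Pipeline configuration and the end-to-end run: simulate -> sample -> metrics -> calibrate.

Configuration is a nested mapping validated fail-fast: unknown keys anywhere
raise immediately, and every run writes the fully resolved configuration next
to its outputs.  All randomness flows from the single master seed recorded in
the manifest, and the manifest lists every output file with its SHA-256
content hash, so a rerun with the same configuration is verifiably identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import calibrate as _cal
from . import metrics as _met
from . import sampling as _smp
from . import simulate as _sim

__all__ = ["DEFAULT_CONFIG", "PipelineConfig", "run_pipeline"]

DEFAULT_CONFIG: dict[str, Any] = {
    "scenario": {
        "days": 3.0,
        "tolerance_preset": "fast",  # strict|fast
        "kindle_start_clock": "21:12",
        "kindle_day": 2,
        "kindle_duration_min": 50.0,
        "pulse_interval_s": 40.0,
        "pulse_intensity": _sim.LHK_PULSE_INTENSITY,
        "sham_k2_multiplier": _sim.SHAM_K2_MULTIPLIER,
    },
    "forcing": {
        "d1": 0.2662,
        "d2": 2.5,
    },
    "sampling": {
        "variant": "B",
        "cv": 0.041,
        "missingness_prob": 0.0,
        "n_per_group": {"control": 3, "sham": 4, "kindled": 4},
        "master_seed": 0,
    },
    "calibration": {
        "enabled": True,
        "pulse_grid": [2e-8, 5e-8, 2e-7],
        "fit_multiplier": False,
        "multiplier_bounds": [1.0, 1.5],
        "multiplier_grid_points": 6,
    },
    "output": {
        "directory": "pipeline_out",
        "log_level": "INFO",
    },
}


def _check_keys(given: Mapping, allowed: Mapping, path: str = "") -> None:
    for key, value in given.items():
        where = f"{path}.{key}" if path else key
        if key not in allowed:
            raise ValueError(f"unknown configuration key: {where!r}")
        if isinstance(allowed[key], Mapping) and key != "n_per_group":
            if not isinstance(value, Mapping):
                raise ValueError(f"configuration section {where!r} must be a mapping")
            _check_keys(value, allowed[key], where)


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict) and key != "n_per_group":
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value) if isinstance(value, (dict, list)) else value
    return out


class PipelineConfig:
    """Validated pipeline configuration (defaults overlaid with user values)."""

    REQUIRED_SECTIONS = ("scenario", "forcing", "sampling", "calibration", "output")

    def __init__(self, overrides: Mapping[str, Any] | None = None):
        overrides = overrides or {}
        _check_keys(overrides, DEFAULT_CONFIG)
        self.data = _merge(DEFAULT_CONFIG, overrides)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        missing = [s for s in cls.REQUIRED_SECTIONS if s not in loaded]
        if missing:
            raise ValueError(f"configuration missing section(s): {missing}")
        return cls(loaded)

    def __getitem__(self, key: str):
        return self.data[key]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _dump_json(data, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2, default=_to_jsonable) + "\n")


def run_pipeline(config: PipelineConfig | Mapping | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run the full in-silico experiment; returns the output manifest.

    Stages: control/sham/LHK simulation, synthetic cohort sampling, oscillation
    metrics, group ANOVA, and (optionally) pulse-intensity / stress-multiplier
    calibration against the synthetic kindled/sham animals.  Any stage failure
    aborts with the stage name; the partial manifest is attached to the error.
    """
    if config is None:
        config = PipelineConfig()
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig(config)
    out = Path(outdir) if outdir is not None else Path(config["output"]["directory"])
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "master_seed": config["sampling"]["master_seed"],
        "stages": [],
        "files": {},
    }

    def record(path: Path) -> None:
        manifest["files"][path.name] = _sha256(path)

    stage = "configure"
    try:
        cfg_path = out / "resolved_config.yaml"
        config.to_yaml(cfg_path)
        record(cfg_path)

        stage = "simulate"
        sc = config["scenario"]
        forcing = _sim.ForcingParams(d1=config["forcing"]["d1"], d2=config["forcing"]["d2"])
        preset = sc["tolerance_preset"]
        days = float(sc["days"])
        kindle_start = _sim.clock_to_minutes(sc["kindle_start_clock"], day=int(sc["kindle_day"]))
        scenarios = {
            "control": _sim.control_scenario(days=days, forcing=forcing),
            "sham": _sim.sham_scenario(
                days=days, k2_multiplier=sc["sham_k2_multiplier"], forcing=forcing
            ),
            "kindled": _sim.lhk_scenario(
                days=days,
                intensity=sc["pulse_intensity"],
                kindle_start=kindle_start,
                kindle_duration_min=sc["kindle_duration_min"],
                pulse_interval_s=sc["pulse_interval_s"],
                k2_multiplier=sc["sham_k2_multiplier"],
                forcing=forcing,
            ),
        }
        trajectories = {}
        for name, scenario in scenarios.items():
            traj = _sim.integrate(scenario.with_tolerances(preset))
            trajectories[name] = traj
            path = out / f"trajectory_{name}.csv"
            traj.to_csv(path)
            record(path)
        manifest["stages"].append("simulate")

        stage = "sample"
        smp = config["sampling"]
        schedule = _smp.make_schedule(
            smp["variant"],
            kindle_start_clock=sc["kindle_start_clock"],
            kindle_day=int(sc["kindle_day"]),
            kindle_duration_min=sc["kindle_duration_min"],
        )
        noise = _smp.NoiseModel(cv=smp["cv"], missingness_prob=smp["missingness_prob"])
        cohort = _smp.make_cohort(
            trajectories,
            n_per_group=dict(smp["n_per_group"]),
            schedule=schedule,
            noise=noise,
            master_seed=int(smp["master_seed"]),
        )
        cohort_path = out / "cohort.csv"
        _smp.cohort_to_frame(cohort).to_csv(cohort_path, index=False, float_format="%.17g")
        record(cohort_path)
        seeds_path = out / "cohort_manifest.json"
        _dump_json(
            {s.animal_id: {"group": s.group, "seed": s.seed} for s in cohort}, seeds_path
        )
        record(seeds_path)
        manifest["stages"].append("sample")

        stage = "metrics"
        window = (1440.0, days * 1440.0)
        all_metrics = {}
        for name, traj in trajectories.items():
            m = _met.detect_ultradian(traj.times, traj.series("CTS"), window=window)
            all_metrics[name] = m.as_dict()
        anova = _cal.group_comparison(cohort)
        metrics_path = out / "metrics.json"
        _dump_json({"oscillations": all_metrics, "anova": asdict(anova)}, metrics_path)
        record(metrics_path)
        manifest["stages"].append("metrics")

        stage = "calibrate"
        cal = config["calibration"]
        if cal["enabled"]:
            kindled = [s for s in cohort if s.group == "kindled"]
            fit = _cal.fit_pulse_intensity(
                kindled,
                candidates=list(cal["pulse_grid"]),
                kindle_start=kindle_start,
                kindle_duration_min=sc["kindle_duration_min"],
                pulse_interval_s=sc["pulse_interval_s"],
                k2_multiplier=sc["sham_k2_multiplier"],
                fast_tolerances=True,
            )
            results = {"pulse_intensity": asdict(fit)}
            if cal["fit_multiplier"]:
                shams = [s for s in cohort if s.group == "sham"]
                mfit = _cal.fit_stress_multiplier(
                    shams,
                    bounds=tuple(cal["multiplier_bounds"]),
                    n_grid=int(cal["multiplier_grid_points"]),
                )
                results["k2_multiplier"] = asdict(mfit)
            cal_path = out / "calibration.json"
            _dump_json(results, cal_path)
            record(cal_path)
            manifest["stages"].append("calibrate")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest_path = out / "manifest.json"
    _dump_json({k: v for k, v in manifest.items()}, manifest_path)
    return manifest
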