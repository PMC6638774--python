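"""Experiment configuration, validation, protocol dispatch and output.

All experiments are described by a plain-text (YAML) configuration with
four blocks — sky, sensor, compass, protocol — plus a master seed and an
output directory.  Angles are degrees everywhere.  Every output table is
accompanied by a manifest (config, config hash, seed, package version,
timings) and the same configuration and seed reproduce byte-identical
tables.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compass_core import CompassModel, GatingParams
from .dra_sensor import DEFAULT_TRANSFORM, build_dra
from .evaluation import (
    EvalProtocol,
    disturbance_curve,
    run_objective,
    sweep_gating,
    sweep_layout,
    sweep_populations,
)
from .rng import substream_seed
from .skylight import Sky, SkyConfig, SunPosition, dome_raster

__all__ = ["ExperimentConfig", "ConfigError", "run"]

PROTOCOLS = (
    "evaluate",
    "disturbance",
    "sweep-gating",
    "sweep-layout",
    "sweep-populations",
    "behave",
    "neurophys",
    "skymap",
)


class ConfigError(ValueError):
    """Invalid experiment configuration; the message names the field."""


@dataclass
class ExperimentConfig:
    """Serialisable description of one experiment run."""

    protocol: str = "evaluate"
    seed: int = 1
    outdir: str = "results"
    sky: dict = field(default_factory=dict)
    sensor: dict = field(default_factory=dict)
    compass: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def validate(self):
        if self.protocol not in PROTOCOLS:
            raise ConfigError(
                f"protocol: unknown value {self.protocol!r} (expected one of {PROTOCOLS})"
            )
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError("seed: must be a non-negative integer")
        for block, allowed in (
            ("sky", {"d_max", "latitude", "longitude", "date", "time", "utc_offset"}),
            ("sensor", {"n", "omega", "rho", "transform"}),
            (
                "compass",
                {"n_sol", "n_tcl", "theta_g", "sigma_g", "gating", "tilt_mode", "time_compensation"},
            ),
        ):
            block_dict = getattr(self, block)
            if not isinstance(block_dict, dict):
                raise ConfigError(f"{block}: must be a mapping")
            for key in block_dict:
                if key not in allowed:
                    raise ConfigError(f"{block}.{key}: unknown field")
        return self

    # -- construction --------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{sorted(unknown)[0]}: unknown top-level field")
        return cls(**data).validate()

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    # -- model factories ----------------------------------------------

    def sky_config(self) -> SkyConfig:
        kw = dict(self.sky)
        if "date" in kw and isinstance(kw["date"], str):
            kw["date"] = _dt.date.fromisoformat(kw["date"])
        if "time" in kw and isinstance(kw["time"], str):
            kw["time"] = _dt.time.fromisoformat(kw["time"])
        try:
            return SkyConfig(**kw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"sky: {exc}") from exc

    def sensor_array(self):
        kw = {k: v for k, v in self.sensor.items() if k != "transform"}
        try:
            return build_dra(**kw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"sensor: {exc}") from exc

    def compass_model(self) -> CompassModel:
        c = dict(self.compass)
        gating = GatingParams(
            theta_g=c.pop("theta_g", 40.0),
            sigma_g=c.pop("sigma_g", 13.0),
            enabled=c.pop("gating", True),
        )
        try:
            return CompassModel(
                self.sensor_array(),
                n_sol=c.pop("n_sol", 8),
                n_tcl=c.pop("n_tcl", 8),
                gating=gating,
                tilt_mode=c.pop("tilt_mode", "calibrated"),
                time_compensation=c.pop("time_compensation", True),
                transform=self.sensor.get("transform", DEFAULT_TRANSFORM),
                sky_config=self.sky_config(),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"compass: {exc}") from exc


def run(config: ExperimentConfig) -> dict:
    """Execute the configured protocol; write CSV tables and a manifest.

    Returns the summary dictionary that is also written as
    ``summary.json`` in the output directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    summary = _DISPATCH[config.protocol](config, outdir)
    summary = {
        "protocol": config.protocol,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "elapsed_s": round(time.perf_counter() - t0, 3),
        **summary,
    }
    manifest = {"config": config.to_dict(), "summary": summary}
    (outdir / "summary.json").write_text(json.dumps(manifest, indent=2, default=str))
    return summary


def _write(df: pd.DataFrame, outdir: Path, name: str):
    df.to_csv(outdir / name, index=False, float_format="%.10g")


def _run_evaluate(config, outdir):
    compass = config.compass_model()
    protocol = EvalProtocol(
        n_sun=int(config.params.get("n_sun", 500)),
        eta=float(config.params.get("eta", 0.0)),
        seed=config.seed,
    )
    res = run_objective(compass, protocol)
    _write(res.records, outdir, "predictions.csv")
    _write(res.by_tilt(), outdir, "by_tilt.csv")
    _write(res.by_elevation(), outdir, "by_elevation.csv")
    return {
        "J": res.J,
        "se": res.se,
        "mean_confidence": res.mean_confidence,
        "n_predictions": len(res.records),
    }


def _run_disturbance(config, outdir):
    compass = config.compass_model()
    etas = config.params.get("etas", [0.0, 0.2, 0.4, 0.6, 0.8, 0.97])
    protocol = EvalProtocol(
        tilts=[(0.0, 0.0)],
        n_sun=int(config.params.get("n_sun", 500)),
        seed=config.seed,
    )
    table = disturbance_curve(
        etas, compass, protocol, n_seeds=int(config.params.get("n_seeds", 5))
    )
    _write(table, outdir, "disturbance.csv")
    return {"etas": list(map(float, etas)), "J": table["J"].tolist()}


def _run_sweep_gating(config, outdir):
    theta_gs = config.params.get("theta_g_grid", list(np.arange(20.0, 61.0, 5.0)))
    sigma_gs = config.params.get("sigma_g_grid", [5.0, 9.0, 13.0, 17.0, 21.0, 26.0, 30.0])
    protocol = EvalProtocol(n_sun=int(config.params.get("n_sun", 100)), seed=config.seed)
    table, argmin = sweep_gating(theta_gs, sigma_gs, protocol, config.sky_config())
    _write(table, outdir, "gating_sweep.csv")
    return {"argmin_theta_g": argmin[0], "argmin_sigma_g": argmin[1]}


def _run_sweep_layout(config, outdir):
    n_grid = config.params.get("n_grid", [12, 24, 36, 48, 60, 90, 120])
    omega_grid = config.params.get("omega_grid", [56.0])
    protocol = EvalProtocol(n_sun=int(config.params.get("n_sun", 100)), seed=config.seed)
    table = sweep_layout(n_grid, omega_grid, protocol, config.sky_config())
    _write(table, outdir, "layout_sweep.csv")
    return {"best_n": int(table.loc[table["J"].idxmin(), "n"])}


def _run_sweep_populations(config, outdir):
    n_sol_grid = config.params.get("n_sol_grid", [4, 8, 16])
    n_tcl_grid = config.params.get("n_tcl_grid", [8])
    protocol = EvalProtocol(n_sun=int(config.params.get("n_sun", 100)), seed=config.seed)
    table = sweep_populations(n_sol_grid, n_tcl_grid, protocol, config.sky_config())
    _write(table, outdir, "population_sweep.csv")
    return {"J_by_n_sol": dict(zip(map(int, table["n_sol"]), table["J"]))}


def _run_behave(config, outdir):
    from .agent_sim import generate_route, generate_terrain, run_trial

    cfg = config.sky_config()
    compass = config.compass_model()
    p = config.params
    route = generate_route(
        feeder_distance=float(p.get("feeder_distance", 7.0)),
        tortuosity=float(p.get("route_tortuosity", 0.6)),
        seed=substream_seed(config.seed, "route"),
    )
    if float(p.get("altitude_sd", 0.8)) > 0:
        terrain = generate_terrain(
            size=float(p.get("arena_size", 10.0)),
            altitude_sd=float(p.get("altitude_sd", 0.8)),
            smoothing=float(p.get("smoothing", 1.9)),
            seed=substream_seed(config.seed, "terrain"),
        )
    else:
        terrain = None
    res = run_trial(
        route.scaled(float(p.get("arena_scale", 1.0))),
        terrain=terrain,
        eta=float(p.get("eta", 0.0)),
        compass=compass,
        time_compensation=bool(p.get("time_compensation", True)),
        sky_config=cfg,
        speed=float(p.get("speed", 0.35)),
        seed=config.seed,
    )
    _write(res.trajectory, outdir, "trajectory.csv")
    return {
        "endpoint_error": res.endpoint_error,
        "feeder_distance": res.feeder_distance,
        "success": bool(res.success),
        "delta_max": res.delta_max,
    }


def _run_neurophys(config, outdir):
    from .neurophys_sim import (
        dominant_period,
        preference_slope,
        rotating_polariser_experiment,
        rotating_sky_experiment,
    )

    compass = config.compass_model()
    p = config.params
    pol = rotating_polariser_experiment(
        compass,
        eta=float(p.get("polariser_eta", 0.1)),
        n_trials=int(p.get("n_trials_polariser", 20)),
        seed=config.seed,
    )
    sky = rotating_sky_experiment(
        compass,
        sun_elevation=float(p.get("sun_elevation", 30.0)),
        eta=float(p.get("sky_eta", 0.5)),
        n_trials=int(p.get("n_trials_sky", 100)),
        seed=config.seed,
    )
    rows = []
    for cond, curves in (("polariser", pol), ("sky", sky)):
        for c in curves:
            for a, r in zip(c.angles, c.response):
                rows.append({"condition": cond, "neuron": c.neuron, "angle": a, "response": r})
    _write(pd.DataFrame(rows), outdir, "tuning_curves.csv")
    prefs = pd.DataFrame(
        [
            {"condition": cond, "neuron": c.neuron, "pref": c.pref, "axial": c.axial}
            for cond, curves in (("polariser", pol), ("sky", sky))
            for c in curves
        ]
    )
    _write(prefs, outdir, "preferred_directions.csv")
    return {
        "polariser_period": float(np.median([dominant_period(c.angles, c.response) for c in pol])),
        "sky_period": float(np.median([dominant_period(c.angles, c.response) for c in sky])),
        "polariser_slope": preference_slope(pol),
        "sky_slope": preference_slope(sky),
    }


def _run_skymap(config, outdir):
    cfg = config.sky_config()
    p = config.params
    if "sun_elevation" in p:
        sun = SunPosition(float(p["sun_elevation"]), float(p.get("sun_azimuth", 180.0)))
    else:
        sun = cfg.sun()
    raster = dome_raster(
        Sky(sun, cfg),
        elevation_step=float(p.get("elevation_step", 1.0)),
        azimuth_step=float(p.get("azimuth_step", 1.0)),
    )
    _write(raster, outdir, "skymap.csv")
    return {
        "sun_elevation": sun.elevation,
        "sun_azimuth": sun.azimuth,
        "max_dop": float(raster["dop"].max()),
    }


_DISPATCH = {
    "evaluate": _run_evaluate,
    "disturbance": _run_disturbance,
    "sweep-gating": _run_sweep_gating,
    "sweep-layout": _run_sweep_layout,
    "sweep-populations": _run_sweep_populations,
    "behave": _run_behave,
    "neurophys": _run_neurophys,
    "skymap": _run_skymap,
}
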