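"""Config parsing, trace serialization, and run manifests.

Configs are YAML or JSON; a config fully determines a run (stochastic
parts via stored seeds), so re-running an archived config reproduces its
outputs bit-identically.  Unknown keys are rejected rather than ignored
— a typo in a parameter name must never silently fall back to a default.
Traces are CSV with a named header; arrays here are small and human
inspectability matters for a modeling tool.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .blocks import GeneratorSpec, KernelSpec, RegulatorSpec
from .circuit import CircuitSpec, Scenario, TraceSet
from .signals import (
    Signal,
    StepSchedule,
    TimeGrid,
    add_white_noise,
    make_constant_profile,
    make_square_wave,
    make_staircase_profile,
    make_step_profile,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_config",
    "write_traces",
    "read_traces",
    "read_unit_traces",
    "write_unit_traces",
    "write_manifest",
]

TRACE_COLUMNS = ("time", "setpoint", "load", "error", "control", "output")

# float format that round-trips float64 exactly
_FLOAT_FMT = "%.17g"


class ConfigError(ValueError):
    """A config file violates the schema; the message names the key."""


def _check_keys(section: dict, allowed: set, where: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigError(
                f"unknown key '{key}' in {where}; allowed keys: {sorted(allowed)}"
            )


_PROFILE_KEYS = {
    "constant": {"level"},
    "step": {"baseline", "segments"},
    "staircase": {"start", "increment", "interval"},
    "square_wave": {"low", "high", "period"},
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run description: circuit, grid, profiles, seeds, mode."""

    circuit: CircuitSpec
    grid: TimeGrid
    setpoint_spec: dict
    load_spec: dict
    engine_mode: str = "exact"
    seed: Optional[int] = None
    raw: Optional[dict] = None

    def build_profile(self, spec: dict) -> Signal:
        return _build_profile(spec, self.grid)

    def build_scenario(self) -> Scenario:
        return Scenario(
            setpoint=self.build_profile(self.setpoint_spec),
            load=self.build_profile(self.load_spec),
        )


def _build_profile(spec: dict, grid: TimeGrid) -> Signal:
    kind = spec["type"]
    if kind == "constant":
        sig = make_constant_profile(spec.get("level", 0.0), grid)
    elif kind == "step":
        schedule = StepSchedule(
            spec.get("baseline", 0.0),
            tuple((seg[0], seg[1]) for seg in spec.get("segments", ())),
        )
        sig = make_step_profile(schedule, grid)
    elif kind == "staircase":
        sig = make_staircase_profile(
            spec["start"], spec["increment"], spec["interval"], grid
        )
    else:  # square_wave
        sig = make_square_wave(spec["low"], spec["high"], spec["period"], grid)
    sigma = spec.get("noise_sigma", 0.0)
    if sigma:
        if "seed" not in spec:
            raise ConfigError(
                "profile with noise_sigma > 0 requires an explicit 'seed'"
            )
        sig = add_white_noise(sig, sigma, spec["seed"])
    return sig


def _parse_profile(section: dict, where: str) -> dict:
    if not isinstance(section, dict):
        raise ConfigError(f"{where} must be a mapping")
    if "type" not in section:
        raise ConfigError(f"missing key 'type' in {where}")
    kind = section["type"]
    if kind not in _PROFILE_KEYS:
        raise ConfigError(
            f"unknown profile type '{kind}' in {where}; "
            f"allowed: {sorted(_PROFILE_KEYS)}"
        )
    _check_keys(
        section, _PROFILE_KEYS[kind] | {"type", "noise_sigma", "seed"}, where
    )
    return dict(section)


def _parse_regulator(section: dict, dt: float) -> RegulatorSpec:
    where = "circuit.regulator"
    if not isinstance(section, dict):
        raise ConfigError(f"{where} must be a mapping")
    _check_keys(
        section, {"kind", "k", "w", "tau", "kernel", "k_d", "saturation"}, where
    )
    if "kind" not in section:
        raise ConfigError(f"missing key 'kind' in {where}")
    kwargs = dict(section)
    if "kernel" in kwargs and kwargs["kernel"] is not None:
        ksec = kwargs["kernel"]
        _check_keys(ksec, {"p_B", "h_A", "h_B"}, f"{where}.kernel")
        if "p_B" not in ksec:
            raise ConfigError(f"missing key 'p_B' in {where}.kernel")
        kwargs["kernel"] = KernelSpec.from_mixture(
            ksec["p_B"], h_A=ksec.get("h_A", 20.0), h_B=ksec.get("h_B", 1.0)
        )
    if "saturation" in kwargs and kwargs["saturation"] is not None:
        kwargs["saturation"] = tuple(kwargs["saturation"])
    try:
        spec = RegulatorSpec(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid {where}: {exc}") from exc
    if spec.w is not None and spec.w < dt:
        raise ConfigError(
            f"regulator window w={spec.w} is shorter than grid dt={dt} "
            f"(the invariant w >= dt must hold)"
        )
    return spec


def read_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run config."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    _check_keys(raw, {"grid", "circuit", "scenario", "engine", "seed"}, "config")

    gsec = raw.get("grid", {})
    _check_keys(gsec, {"t0", "dt", "horizon", "n_steps"}, "grid")
    dt = gsec.get("dt", 0.01)
    t0 = gsec.get("t0", 0.0)
    try:
        if "n_steps" in gsec:
            if "horizon" in gsec:
                raise ConfigError("grid takes either 'horizon' or 'n_steps', not both")
            grid = TimeGrid(t0=t0, dt=dt, n_steps=gsec["n_steps"])
        else:
            grid = TimeGrid.from_horizon(gsec.get("horizon", 100.0), dt=dt, t0=t0)
    except ValueError as exc:
        raise ConfigError(f"invalid grid: {exc}") from exc

    csec = raw.get("circuit")
    if not isinstance(csec, dict):
        raise ConfigError("config requires a 'circuit' mapping")
    _check_keys(csec, {"topology", "load_injection", "regulator", "generator"}, "circuit")
    if "regulator" not in csec:
        raise ConfigError("missing key 'regulator' in circuit")
    regulator = _parse_regulator(csec["regulator"], dt=grid.dt)
    generator = None
    if "generator" in csec and csec["generator"] is not None:
        gen_sec = csec["generator"]
        _check_keys(gen_sec, {"g_c"}, "circuit.generator")
        generator = GeneratorSpec(**gen_sec)
    try:
        circuit = CircuitSpec(
            topology=csec.get("topology", "basic"),
            regulator=regulator,
            generator=generator,
            load_injection=csec.get("load_injection", "at_generator"),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid circuit: {exc}") from exc

    ssec = raw.get("scenario")
    if not isinstance(ssec, dict):
        raise ConfigError("config requires a 'scenario' mapping")
    _check_keys(ssec, {"setpoint", "load"}, "scenario")
    if "setpoint" not in ssec:
        raise ConfigError("missing key 'setpoint' in scenario")
    setpoint_spec = _parse_profile(ssec["setpoint"], "scenario.setpoint")
    load_spec = _parse_profile(
        ssec.get("load", {"type": "constant", "level": 0.0}), "scenario.load"
    )

    esec = raw.get("engine", {})
    _check_keys(esec, {"mode"}, "engine")
    mode = esec.get("mode", "exact")
    if mode not in ("exact", "delayed"):
        raise ConfigError(f"engine.mode must be 'exact' or 'delayed', got '{mode}'")

    config = RunConfig(
        circuit=circuit,
        grid=grid,
        setpoint_spec=setpoint_spec,
        load_spec=load_spec,
        engine_mode=mode,
        seed=raw.get("seed"),
        raw=raw,
    )
    # validate that the profiles actually render on this grid
    try:
        config.build_scenario()
    except ValueError as exc:
        raise ConfigError(f"invalid scenario: {exc}") from exc
    return config


def write_traces(traces: TraceSet, path) -> None:
    traces.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def _grid_from_times(time: np.ndarray, where: str) -> TimeGrid:
    if time.size < 2:
        raise ValueError(f"{where}: need at least 2 samples")
    dt = float((time[-1] - time[0]) / (time.size - 1))
    if not np.allclose(np.diff(time), dt, rtol=1e-6, atol=1e-9 * max(dt, 1)):
        raise ValueError(f"{where}: time column is not uniformly sampled")
    return TimeGrid(t0=float(time[0]), dt=dt, n_steps=int(time.size))


def read_traces(path) -> TraceSet:
    """Read a trace CSV (columns matched by name, any order)."""
    df = pd.read_csv(path)
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"trace file {path} is missing column '{col}'")
    grid = _grid_from_times(df["time"].to_numpy(), str(path))
    return TraceSet(
        grid=grid,
        **{
            name: Signal(grid, df[name].to_numpy())
            for name in TRACE_COLUMNS
            if name != "time"
        },
    )


def read_unit_traces(path) -> Dict[str, Signal]:
    """Read a per-unit trace CSV: column 'time' plus one column per unit."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"unit trace file {path} is missing column 'time'")
    units = [c for c in df.columns if c != "time"]
    if not units:
        raise ValueError(f"unit trace file {path} has no unit columns")
    grid = _grid_from_times(df["time"].to_numpy(), str(path))
    return {u: Signal(grid, df[u].to_numpy()) for u in units}


def write_unit_traces(units: Dict[str, Signal], path) -> None:
    grids = {u: s.grid for u, s in units.items()}
    first = next(iter(grids.values()))
    if any(g != first for g in grids.values()):
        raise ValueError("all unit signals must share one grid")
    df = pd.DataFrame({"time": first.times})
    for u, s in units.items():
        df[u] = s.values
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_manifest(path, config: Optional[dict] = None, **extra) -> None:
    """Write a JSON manifest (config echo, hash, seeds, versions, mode)."""
    from . import __version__

    payload = {"arousalctl_version": __version__}
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str)
        payload["config"] = config
        payload["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
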