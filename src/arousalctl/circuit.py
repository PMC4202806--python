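"""Closed-loop wiring of comparator-regulator-generator and its oracles.

Two topologies are supported.  In the *basic* loop the comparator feeds
the regulator only and the generator sums control signal and load.  In
the *feedforward* topology the comparator also projects directly to the
generator (gain ``g_c``), mirroring orexin cells synapsing onto both
putative regulators (histamine) and putative generators (noradrenaline).

The engine is fixed-step.  At every step the algebraic summing points
(comparator and generator) are solved *exactly* as a scalar linear fixed
point over the instantaneous paths, rather than broken with a unit
delay; state-bearing regulators contribute through lagged state only.
A one-step-delay mode is available for comparison.  ``dc_solve`` is the
closed-form steady-state oracle for every linear configuration, and
``check_stability`` reports the spectral radius of the engine's discrete
update map.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional

import numpy as np

from .blocks import GeneratorSpec, RegulatorSpec, RegulatorState, dc_gain
from .signals import Signal, TimeGrid

__all__ = [
    "CircuitSpec",
    "Scenario",
    "TraceSet",
    "DCOperatingPoint",
    "StabilityReport",
    "SimulationDiverged",
    "UnstableCircuitError",
    "simulate",
    "dc_solve",
    "check_stability",
]

TOPOLOGIES = ("basic", "feedforward")
INJECTION_POINTS = ("at_generator", "at_comparator", "at_regulator_input")

#: divergence guard threshold multiplier
_GUARD = 1e6


class SimulationDiverged(RuntimeError):
    """Raised when the loop output exceeds the divergence guard."""


class UnstableCircuitError(RuntimeError):
    """Raised when simulating a configuration flagged unstable."""


@dataclass(frozen=True)
class CircuitSpec:
    """Loop topology plus block parameters.

    The basic topology forces ``g_c = 0``; the feedforward topology
    requires ``g_c > 0``.  ``load_injection`` selects where the load
    enters the loop (default: the final summing point at the generator;
    a load injected at the comparator is processed as if it were a
    set-point change — the loop's known weak point).
    """

    topology: str = "basic"
    regulator: RegulatorSpec = field(
        default_factory=lambda: RegulatorSpec("proportional", k=1.0)
    )
    generator: Optional[GeneratorSpec] = None
    load_injection: str = "at_generator"

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"unknown topology '{self.topology}'; choose from {TOPOLOGIES}"
            )
        if self.load_injection not in INJECTION_POINTS:
            raise ValueError(
                f"unknown load_injection '{self.load_injection}'; "
                f"choose from {INJECTION_POINTS}"
            )
        gen = self.generator
        if gen is None:
            gen = GeneratorSpec(g_c=0.0 if self.topology == "basic" else 1.0)
            object.__setattr__(self, "generator", gen)
        if self.topology == "basic" and gen.g_c != 0:
            raise ValueError(
                f"basic topology forces g_c = 0, got g_c = {gen.g_c}"
            )
        if self.topology == "feedforward" and not gen.g_c > 0:
            raise ValueError(
                f"feedforward topology requires g_c > 0, got g_c = {gen.g_c}"
            )

    @property
    def g_c(self) -> float:
        return self.generator.g_c


@dataclass(frozen=True)
class Scenario:
    """Set-point and load signals on a shared grid."""

    setpoint: Signal
    load: Signal

    def __post_init__(self) -> None:
        if self.setpoint.grid != self.load.grid:
            raise ValueError("set-point and load must share the same time grid")

    @property
    def grid(self) -> TimeGrid:
        return self.setpoint.grid


@dataclass(frozen=True)
class TraceSet:
    """Aligned per-node signals from one simulation."""

    grid: TimeGrid
    setpoint: Signal
    load: Signal
    error: Signal
    control: Signal
    output: Signal

    def __post_init__(self) -> None:
        for name in ("setpoint", "load", "error", "control", "output"):
            if getattr(self, name).grid != self.grid:
                raise ValueError(f"trace '{name}' is not on the shared grid")

    def node_signals(self) -> dict:
        """Per-node activity keyed by control role: C (error node),
        R (control node), G (output node)."""
        return {"C": self.error, "R": self.control, "G": self.output}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.grid.times,
                "setpoint": self.setpoint.values,
                "load": self.load.values,
                "error": self.error.values,
                "control": self.control.values,
                "output": self.output.values,
            }
        )


class DCOperatingPoint(NamedTuple):
    error: float
    control: float
    output: float


@dataclass(frozen=True)
class StabilityReport:
    stable: bool
    spectral_radius: Optional[float]
    margin: Optional[float]
    heuristic: bool = False
    note: str = ""


def simulate(
    circuit: CircuitSpec,
    scenario: Scenario,
    *,
    engine_mode: str = "exact",
    check: bool = True,
) -> TraceSet:
    """Run the closed loop over the scenario and return all node traces.

    Per step: (1) evaluate the state-determined part of the control
    signal; (2) solve the scalar linear fixed point over instantaneous
    paths for the error; (3) form the generator output; (4) advance the
    regulator state.  The comparator identity ``e = r - y`` (plus the
    load, when it is injected at the comparator) holds to machine
    precision by construction.

    Parameters
    ----------
    engine_mode : {"exact", "delayed"}
        "exact" solves the summing points algebraically each step;
        "delayed" breaks the loop with a unit delay (for comparison).
    check : bool
        Run :func:`check_stability` first and refuse unstable
        configurations; pass ``check=False`` to override.
    """
    if engine_mode not in ("exact", "delayed"):
        raise ValueError(f"unknown engine_mode '{engine_mode}'")
    if check:
        report = check_stability(circuit, scenario.grid)
        if not report.stable:
            raise UnstableCircuitError(
                f"configuration flagged unstable (spectral radius "
                f"{report.spectral_radius}); pass check=False to override"
            )

    grid = scenario.grid
    n = grid.n_steps
    r = scenario.setpoint.values
    d = scenario.load.values
    g_c = circuit.g_c
    injection = circuit.load_injection
    sat = circuit.regulator.saturation

    reg = RegulatorState(circuit.regulator, grid)
    k_inst = reg.k_inst
    den = 1.0 + g_c + k_inst

    e_arr = np.empty(n)
    u_arr = np.empty(n)
    y_arr = np.empty(n)
    guard = _GUARD * max(np.max(np.abs(r)), np.max(np.abs(d)), 1.0)

    state_output = reg.state_output
    update = reg.update
    exact = engine_mode == "exact"

    y_prev = 0.0
    for i in range(n):
        u_state = state_output()
        ri = r[i]
        di = d[i]
        if exact:
            if injection == "at_generator":
                e = (ri - u_state - di) / den
            elif injection == "at_comparator":
                e = (ri + di - u_state) / den
            else:  # at_regulator_input
                e = (ri - u_state - k_inst * di) / den
        else:
            if injection == "at_comparator":
                e = ri - y_prev + di
            else:
                e = ri - y_prev

        reg_in = e + di if injection == "at_regulator_input" else e
        u = u_state + k_inst * reg_in
        if sat is not None:
            u_c = min(max(u, sat[0]), sat[1])
            if u_c != u and exact:
                # clipped control is a constant: re-solve the remaining
                # comparator/generator fixed point consistently
                if injection == "at_generator":
                    e = (ri - u_c - di) / (1.0 + g_c)
                elif injection == "at_comparator":
                    e = (ri + di - u_c) / (1.0 + g_c)
                else:
                    e = (ri - u_c) / (1.0 + g_c)
                reg_in = e + di if injection == "at_regulator_input" else e
            u = u_c
        if exact:
            # enforce the comparator identity bitwise: e was solved so that
            # u + g_c*e (+d) == r - e (+d at the comparator) up to rounding
            y = (ri + di - e) if injection == "at_comparator" else (ri - e)
        else:
            y = u + g_c * e + (di if injection == "at_generator" else 0.0)

        if abs(y) > guard:
            raise SimulationDiverged(
                f"output |y|={abs(y):.3g} exceeded the divergence guard at "
                f"t={grid.t0 + i * grid.dt:.4g} (step {i}); the configuration "
                f"is unstable"
            )
        e_arr[i] = e
        u_arr[i] = u
        y_arr[i] = y
        y_prev = y
        update(reg_in)

    return TraceSet(
        grid=grid,
        setpoint=scenario.setpoint,
        load=scenario.load,
        error=Signal(grid, e_arr),
        control=Signal(grid, u_arr),
        output=Signal(grid, y_arr),
    )


def dc_solve(
    circuit: CircuitSpec,
    r_const: float,
    d_const: float,
    horizon: Optional[float] = None,
) -> DCOperatingPoint:
    """Closed-form steady state of the linear loop under constant inputs.

    With finite regulator DC gain ``G`` the algebraic system is solved
    directly; a window integrator whose window covers the run horizon is
    flagged as infinite DC gain (perfect integral action), which drives
    the regulator's steady input to zero.

    Pass ``horizon`` (the simulated span) so over-horizon windows are
    recognized; with ``horizon=None`` a window integrator is treated as
    the finite-gain filter it is, ``G = k*w``.
    """
    if not circuit.regulator.is_linear:
        raise ValueError(
            "dc_solve handles linear configurations only (saturation enabled)"
        )
    r = float(r_const)
    d = float(d_const)
    g_c = circuit.g_c
    G = dc_gain(circuit.regulator, horizon=horizon)
    inj = circuit.load_injection

    if math.isinf(G):
        # integral action drives the regulator input to zero
        if inj == "at_generator":
            e = 0.0
            y = r
            u = y - g_c * e - d
        elif inj == "at_comparator":
            e = 0.0
            y = r + d  # load at the comparator masquerades as set-point
            u = y - g_c * e
        else:  # at_regulator_input: regulator input e + d -> 0
            e = -d
            y = r - e
            u = y - g_c * e
        return DCOperatingPoint(e, u, y)

    den = 1.0 + g_c + G
    if inj == "at_generator":
        e = (r - d) / den
        u = G * e
        y = r - e
    elif inj == "at_comparator":
        e = (r + d) / den
        u = G * e
        y = r + d - e
    else:  # at_regulator_input
        e = (r - G * d) / den
        u = G * (e + d)
        y = r - e
    return DCOperatingPoint(e, u, y)


def _linear_update_map(circuit: CircuitSpec, grid: TimeGrid):
    """Homogeneous one-step update of the engine's internal state.

    Returns ``(dim, step)`` where ``step`` maps a state vector to the
    next one with r = d = 0.  State layout per regulator kind: window
    integrator -> ring-buffer entries (or a single accumulator when the
    window covers the run); kernel -> one leaky state per component;
    lowpass -> filter state; plus two error lags when k_d > 0.
    """
    spec = circuit.regulator
    g_c = circuit.g_c
    dt = grid.dt
    k = spec.k
    k_d = spec.k_d
    lags = 2 if k_d > 0 else 0
    k_inst = k if spec.kind == "proportional" else 0.0
    den = 1.0 + g_c + k_inst

    if spec.kind == "proportional":
        core = 0
    elif spec.kind == "window_integral":
        m = max(1, int(round(spec.w / dt)))
        core = 1 if m >= grid.n_steps else m
    elif spec.kind == "kernel_integral":
        core = len(spec.kernel.components)
    else:  # lowpass
        core = 1

    dim = core + lags
    if dim == 0:
        return 0, None

    if spec.kind == "kernel_integral":
        decay = np.exp(-spec.kernel.rates * dt)
        weights = spec.kernel.weights
    if spec.kind == "lowpass":
        alpha = math.exp(-dt / spec.tau)

    def step(x: np.ndarray) -> np.ndarray:
        if k_d > 0:
            e1, e2 = x[core], x[core + 1]
            deriv = k_d * (e1 - e2) / dt
        else:
            deriv = 0.0
        if spec.kind == "proportional":
            u_state = deriv
        elif spec.kind == "window_integral":
            u_state = k * float(np.sum(x[:core])) + deriv
        elif spec.kind == "kernel_integral":
            u_state = k * float(np.dot(weights, x[:core])) + deriv
        else:
            u_state = float(x[0]) + deriv
        e = -u_state / den
        out = np.empty(dim)
        if spec.kind == "proportional":
            pass
        elif spec.kind == "window_integral":
            if core == 1:
                out[0] = x[0] + e * dt
            else:
                out[: core - 1] = x[1:core]  # evict oldest
                out[core - 1] = e * dt
        elif spec.kind == "kernel_integral":
            out[:core] = x[:core] * decay + e * dt
        else:
            out[0] = alpha * x[0] + k * (1.0 - alpha) * e
        if k_d > 0:
            out[core] = e
            out[core + 1] = e1
        return out

    return dim, step


def check_stability(circuit: CircuitSpec, grid: TimeGrid) -> StabilityReport:
    """Spectral-radius stability check of the engine's discrete recursion.

    Linear configurations are analyzed exactly (the update map's
    spectral radius must be < 1).  Nonlinear configurations (saturation
    enabled) fall back to a short empirical probe simulation, flagged
    as heuristic.
    """
    if not circuit.regulator.is_linear:
        return _empirical_probe(circuit, grid)

    dim, step = _linear_update_map(circuit, grid)
    if dim == 0:
        # memoryless loop: the exact per-step solve has no dynamics
        return StabilityReport(stable=True, spectral_radius=0.0, margin=1.0)

    if dim <= 800:
        cols = [step(col) for col in np.eye(dim)]
        radius = float(np.max(np.abs(np.linalg.eigvals(np.array(cols).T))))
    else:
        radius = _power_radius(step, dim)
    return StabilityReport(
        stable=radius < 1.0, spectral_radius=radius, margin=1.0 - radius
    )


def _power_radius(step: Callable, dim: int, iters: int = 2000) -> float:
    """Power-iteration estimate of the dominant eigenvalue magnitude."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal(dim)
    x /= np.linalg.norm(x)
    radius = 0.0
    for _ in range(iters):
        y = step(x)
        nrm = np.linalg.norm(y)
        if nrm == 0:
            return 0.0
        radius = nrm
        x = y / nrm
    return float(radius)


def _empirical_probe(circuit: CircuitSpec, grid: TimeGrid) -> StabilityReport:
    from .signals import make_constant_profile

    probe_grid = TimeGrid.from_horizon(
        min(grid.duration, 50.0), dt=grid.dt, t0=grid.t0
    )
    scenario = Scenario(
        setpoint=make_constant_profile(1.0, probe_grid),
        load=make_constant_profile(0.5, probe_grid),
    )
    try:
        traces = simulate(circuit, scenario, check=False)
    except SimulationDiverged:
        return StabilityReport(
            stable=False, spectral_radius=None, margin=None, heuristic=True,
            note="probe simulation diverged",
        )
    tail = np.abs(traces.output.values[-probe_grid.n_steps // 4 :])
    bounded = bool(np.max(tail) <= 10.0)
    return StabilityReport(
        stable=bounded, spectral_radius=None, margin=None, heuristic=True,
        note="empirical probe (nonlinear configuration)",
    )
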