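"""Half-life tuning: transmitter mixtures, integration windows, tracking.

Orexin-A and orexin-B activate the anti-narcoleptic OXR2 receptor with
equal potency, but orexin-A's two disulfide bonds should make it much
harder to degrade.  If regulators integrate orexin-communicated error
over a window set by transmitter lifetime, the released A/B mixture is a
tuning knob: more short-lived B peptide shortens the effective window
``w_eff = sum_i p_i / lambda_i`` and speeds tracking; more long-lived A
peptide lengthens it and buys steady-state precision at the cost of
sluggish, persistent control.  This module quantifies that trade-off by
sweeping the mixture fraction against square-wave environments of
different switching timescales and scoring integrated tracking error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .blocks import KernelSpec, RegulatorSpec, effective_window
from .circuit import CircuitSpec, Scenario, check_stability, simulate
from .signals import TimeGrid, make_constant_profile, make_square_wave

__all__ = [
    "EnvironmentSpec",
    "SweepResult",
    "MixtureOptimum",
    "tracking_error",
    "sweep_mixture",
    "optimal_mixture",
]

METRICS = ("ISE", "IAE")


@dataclass(frozen=True)
class EnvironmentSpec:
    """A square-wave world: set-point alternates low/high every period/2.

    The switching period models the typical duration of salient inputs
    and disturbances the animal's environment serves up (seconds of
    crossing a busy street vs minutes of laughter, rescaled to t.u.).
    """

    period: float
    low: float = 0.5
    high: float = 1.5
    horizon: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ValueError(f"period must be positive, got {self.period}")
        if self.horizon is None:
            object.__setattr__(self, "horizon", 3.0 * self.period)
        if self.horizon < 3.0 * self.period:
            raise ValueError(
                f"horizon {self.horizon} must be >= 3*period = {3 * self.period}"
            )
        if self.name is None:
            object.__setattr__(self, "name", f"P{self.period:g}")


def tracking_error(
    circuit: CircuitSpec,
    env: EnvironmentSpec,
    metric: str = "ISE",
    dt: float = 0.01,
) -> float:
    """Integrated tracking error of the loop in a square-wave environment.

    Simulates with the environment's set-point and zero load, then
    integrates ``(y - r)**2`` (ISE) or ``|y - r|`` (IAE) over the
    horizon, excluding a burn-in of one half-period so the score
    reflects steady cyclic behavior rather than the initial ramp.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got '{metric}'")
    if env.period < 2 * dt:
        raise ValueError(f"period {env.period} must be >= 2*dt = {2 * dt}")
    grid = TimeGrid.from_horizon(env.horizon, dt=dt)
    setpoint = make_square_wave(env.low, env.high, env.period, grid)
    scenario = Scenario(setpoint=setpoint, load=make_constant_profile(0.0, grid))
    traces = simulate(circuit, scenario)
    burn = min(env.period / 2.0, env.horizon / 2.0)
    i0 = grid.index_at(grid.t0 + burn)
    err = traces.output.values[i0:] - setpoint.values[i0:]
    if metric == "ISE":
        return float(np.sum(err**2) * dt)
    return float(np.sum(np.abs(err)) * dt)


@dataclass(frozen=True)
class SweepResult:
    """One row per (mixture fraction, environment): window and tracking error."""

    table: pd.DataFrame  # columns: p_B, w_eff, environment, metric, tracking_error, stable

    def for_environment(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["environment"] == name]
        if sub.empty:
            raise KeyError(f"environment '{name}' not in sweep")
        return sub


@dataclass(frozen=True)
class MixtureOptimum:
    p_B: float
    w_eff: float
    tracking_error: float
    tie: bool


def sweep_mixture(
    p_B_grid: Sequence[float],
    h_A: float = 20.0,
    h_B: float = 1.0,
    k: float = 1.0,
    environments: Sequence[EnvironmentSpec] = (),
    metric: str = "ISE",
    dt: float = 0.01,
) -> SweepResult:
    """Tracking error across a grid of orexin-B fractions and environments.

    The gain ``k`` is held fixed across the grid (no DC-gain
    renormalization), preserving the physiological trade-off: long
    kernels accumulate more (high DC gain) but respond and release
    sluggishly.  Unstable cells are flagged in place, never dropped.
    """
    grid = np.asarray(sorted(float(p) for p in p_B_grid))
    if grid.size < 11:
        raise ValueError(f"p_B grid needs >= 11 points, got {grid.size}")
    if not (math.isclose(grid[0], 0.0) and math.isclose(grid[-1], 1.0)):
        raise ValueError(
            f"p_B grid must cover [0, 1] including both endpoints, got "
            f"[{grid[0]}, {grid[-1]}]"
        )
    if not environments:
        raise ValueError("at least one environment is required")

    rows = []
    for p_B in grid:
        kernel = KernelSpec.from_mixture(p_B, h_A=h_A, h_B=h_B)
        reg = RegulatorSpec("kernel_integral", k=k, kernel=kernel)
        circuit = CircuitSpec(topology="basic", regulator=reg)
        w_eff = effective_window(kernel)
        for env in environments:
            env_grid = TimeGrid.from_horizon(env.horizon, dt=dt)
            stable = check_stability(circuit, env_grid).stable
            err = (
                tracking_error(circuit, env, metric=metric, dt=dt)
                if stable
                else math.nan
            )
            rows.append(
                {
                    "p_B": float(p_B),
                    "w_eff": w_eff,
                    "environment": env.name,
                    "metric": metric,
                    "tracking_error": err,
                    "stable": stable,
                }
            )
    return SweepResult(pd.DataFrame(rows))


def optimal_mixture(sweep: SweepResult, environment: str) -> MixtureOptimum:
    """Argmin of tracking error over the mixture grid for one environment.

    Ties break toward larger ``p_B`` (the shorter window) and are
    flagged.  The minimum and its grid neighbors must be stable.
    """
    sub = sweep.for_environment(environment).sort_values("p_B").reset_index(drop=True)
    if not sub["stable"].any():
        raise ValueError(f"all cells unstable for environment '{environment}'")
    errs = sub["tracking_error"].to_numpy()
    stable = sub["stable"].to_numpy()
    masked = np.where(stable, errs, np.inf)
    best_err = float(np.min(masked))
    winners = np.flatnonzero(masked == best_err)
    idx = int(winners[-1])  # ties -> larger p_B
    for nb in (idx - 1, idx + 1):
        if 0 <= nb < len(sub) and not stable[nb]:
            raise ValueError(
                f"minimum at p_B={sub.loc[idx, 'p_B']} has an unstable "
                f"neighbor (p_B={sub.loc[nb, 'p_B']})"
            )
    return MixtureOptimum(
        p_B=float(sub.loc[idx, "p_B"]),
        w_eff=float(sub.loc[idx, "w_eff"]),
        tracking_error=best_err,
        tie=bool(winners.size > 1),
    )
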