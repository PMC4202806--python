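"""Time grids, deterministic input profiles, and noise injection.

Every experiment in the package is driven by two input signals on a shared
uniform time grid: a *set-point* (the desired arousal level, shaped by
demands such as stress, CO2, glucose, or time of day) and a *load/noise*
signal (anything opposing the arousal generators, e.g. inhibition from
sleep-promoting circuits).  This module provides the grid, the piecewise
profile builders used as probe protocols (steps, staircases, square waves),
and seeded additive Gaussian noise.

Time is dimensionless ("time units", t.u.) and activity is in arbitrary
units (a.u.); nothing in the loop dynamics fixes a physical scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeGrid",
    "Signal",
    "StepSchedule",
    "make_constant_profile",
    "make_step_profile",
    "make_staircase_profile",
    "make_square_wave",
    "add_white_noise",
]

# tolerance (in units of dt) for snapping event times onto grid samples
_SNAP = 1e-9


@dataclass(frozen=True)
class TimeGrid:
    """Uniformly sampled time axis with samples at ``t0 + i*dt``.

    Parameters
    ----------
    t0 : float
        Time of the first sample (t.u.).
    dt : float
        Sampling step (t.u.); must be positive.
    n_steps : int
        Number of samples; must be at least 2.
    """

    t0: float = 0.0
    dt: float = 0.01
    n_steps: int = 10_001

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")

    @classmethod
    def from_horizon(cls, horizon: float, dt: float = 0.01, t0: float = 0.0) -> "TimeGrid":
        """Grid covering ``[t0, t0 + horizon]`` inclusive at step ``dt``."""
        if horizon <= 0:
            raise ValueError(f"horizon must be positive, got {horizon}")
        return cls(t0=t0, dt=dt, n_steps=int(round(horizon / dt)) + 1)

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + i*dt`` (exactly reproducible)."""
        return self.t0 + self.dt * np.arange(self.n_steps)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.n_steps - 1)

    @property
    def duration(self) -> float:
        """Span covered by the grid, ``(n_steps - 1) * dt``."""
        return self.dt * (self.n_steps - 1)

    def index_at(self, t: float) -> int:
        """Index of the first sample at or after time ``t``.

        A time within a tiny tolerance below a sample snaps onto it, so
        event onsets specified at exact sample times are left-closed.
        """
        if t < self.t0 - _SNAP * self.dt or t > self.t_end + _SNAP * self.dt:
            raise ValueError(
                f"time {t} outside grid span [{self.t0}, {self.t_end}]"
            )
        i = int(np.ceil((t - self.t0) / self.dt - _SNAP))
        return min(max(i, 0), self.n_steps - 1)


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled time series: a grid plus one value per sample."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError(f"signal values must be 1-D, got shape {v.shape}")
        if v.size != self.grid.n_steps:
            raise ValueError(
                f"signal length {v.size} does not match grid n_steps {self.grid.n_steps}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("signal values must all be finite")
        object.__setattr__(self, "values", v)

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    def with_values(self, values: np.ndarray) -> "Signal":
        """New signal on the same grid."""
        return Signal(self.grid, values)

    def slice_from(self, t: float) -> "Signal":
        """Sub-signal starting at the first sample at or after ``t``."""
        i = self.grid.index_at(t)
        if self.grid.n_steps - i < 2:
            raise ValueError(f"slice from t={t} leaves fewer than 2 samples")
        sub = TimeGrid(
            t0=self.grid.t0 + i * self.grid.dt,
            dt=self.grid.dt,
            n_steps=self.grid.n_steps - i,
        )
        return Signal(sub, self.values[i:].copy())

    def tail_mean(self, fraction: float = 0.1) -> float:
        """Mean over the trailing ``fraction`` of samples."""
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        n_tail = max(1, int(round(fraction * self.grid.n_steps)))
        return float(np.mean(self.values[-n_tail:]))


@dataclass(frozen=True)
class StepSchedule:
    """Baseline level plus a list of ``(onset_time, new_level)`` segments.

    Onset times must be strictly increasing; whether they lie inside the
    grid span is checked when the schedule is rendered onto a grid.
    """

    baseline: float
    segments: tuple = ()

    def __post_init__(self) -> None:
        segs = tuple((float(t), float(v)) for t, v in self.segments)
        onsets = [t for t, _ in segs]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError(f"step onsets must be strictly increasing, got {onsets}")
        object.__setattr__(self, "segments", segs)


def make_constant_profile(level: float, grid: TimeGrid) -> Signal:
    """Constant signal at ``level``."""
    return Signal(grid, np.full(grid.n_steps, float(level)))


def make_step_profile(schedule: StepSchedule, grid: TimeGrid) -> Signal:
    """Piecewise-constant signal from a step schedule.

    The convention is left-closed: the value at exactly the onset sample
    is the new level.
    """
    values = np.full(grid.n_steps, float(schedule.baseline))
    for onset, level in schedule.segments:
        if onset < grid.t0 - _SNAP * grid.dt or onset > grid.t_end + _SNAP * grid.dt:
            raise ValueError(
                f"step onset {onset} outside grid span [{grid.t0}, {grid.t_end}]"
            )
        values[grid.index_at(onset):] = level
    return Signal(grid, values)


def make_staircase_profile(
    start: float, increment: float, interval: float, grid: TimeGrid
) -> Signal:
    """Escalating (or descending) staircase: a new level every ``interval``.

    ``value(t) = start + increment * floor((t - t0) / interval)``.
    """
    if interval < grid.dt:
        raise ValueError(
            f"staircase interval {interval} must be >= grid dt {grid.dt}"
        )
    steps = np.floor((grid.times - grid.t0) / interval + _SNAP)
    return Signal(grid, start + increment * steps)


def make_square_wave(low: float, high: float, period: float, grid: TimeGrid) -> Signal:
    """Square wave alternating ``low``/``high``, each held for ``period/2``.

    Starts at ``low``; models an environment that switches its demands on
    a characteristic timescale ``period``.
    """
    if period < 2 * grid.dt:
        raise ValueError(
            f"square-wave period {period} must be >= 2*dt = {2 * grid.dt}"
        )
    phase = np.mod((grid.times - grid.t0) / period + _SNAP, 1.0)
    return Signal(grid, np.where(phase < 0.5, float(low), float(high)))


def add_white_noise(signal: Signal, sigma: float, seed: int) -> Signal:
    """Add independent zero-mean Gaussian noise per sample.

    ``sigma = 0`` returns the input unchanged; identical ``seed`` yields
    bitwise-identical output.  The seed is mandatory: every stochastic
    call in the package is reproducible by construction.
    """
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return signal
    rng = np.random.default_rng(seed)
    return signal.with_values(
        signal.values + rng.normal(0.0, sigma, signal.grid.n_steps)
    )
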