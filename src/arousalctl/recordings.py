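"""Synthetic unit recordings: simulated rates -> spikes -> estimated rates.

In vivo, control roles would be diagnosed from extracellular unit
recordings, not from the clean node activities a simulation emits.  This
module emulates that measurement chain: a node's simulated activity is
mapped affinely to a firing rate, spikes are drawn from an inhomogeneous
Poisson process (thinning), and a rate estimate is recovered by binning
and Gaussian smoothing.  The round trip injects realistic Poisson
sampling noise into the classification pipeline without any dataset.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .circuit import TraceSet
from .signals import Signal, TimeGrid

__all__ = [
    "SpikeTrain",
    "RateMap",
    "spikes_from_rate",
    "rate_from_spikes",
    "recording_from_traces",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted event times within a recording span (t0, t_end)."""

    times: np.ndarray
    span: Tuple[float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        t0, t_end = float(self.span[0]), float(self.span[1])
        if t_end <= t0:
            raise ValueError(f"empty recording span {self.span}")
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < t0 or t[-1] > t_end):
            raise ValueError("spike times must lie within the recording span")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "span", (t0, t_end))

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RateMap:
    """Affine map from node activity (a.u.) to firing rate (events/t.u.).

    ``rate = max(0, r0 + gain * activity)``; rates are clipped at zero
    because firing rates are nonnegative.  Heavy clipping distorts
    temporal signatures, so the clipped fraction is logged.
    """

    r0: float = 5.0
    gain: float = 10.0

    def __post_init__(self) -> None:
        if self.r0 < 0:
            raise ValueError(f"baseline rate r0 must be >= 0, got {self.r0}")

    def apply(self, activity: Signal) -> Signal:
        raw = self.r0 + self.gain * activity.values
        clipped_fraction = float(np.mean(raw < 0))
        if clipped_fraction > 0:
            # heavy clipping distorts temporal signatures
            level = logging.WARNING if clipped_fraction > 0.10 else logging.INFO
            logger.log(
                level,
                "rate map clipped %.1f%% of samples at zero rate",
                100 * clipped_fraction,
            )
        return activity.with_values(np.maximum(raw, 0.0))


def spikes_from_rate(rate: Signal, seed: int) -> SpikeTrain:
    """Inhomogeneous Poisson spike train via thinning.

    Candidates are drawn from a homogeneous process at the rate maximum
    and accepted with probability ``rate(t) / rate_max``; the rate is
    treated as piecewise-constant between samples, for which thinning is
    exact.  Identical ``(rate, seed)`` gives identical event times.
    """
    v = rate.values
    if np.any(v < 0):
        raise ValueError("firing rate must be nonnegative everywhere")
    grid = rate.grid
    t0, t_end = grid.t0, grid.t_end
    lam_max = float(np.max(v))
    if lam_max == 0:
        return SpikeTrain(np.empty(0), (t0, t_end))
    rng = np.random.default_rng(seed)
    n_cand = rng.poisson(lam_max * (t_end - t0))
    cand = np.sort(rng.uniform(t0, t_end, n_cand))
    idx = np.minimum(
        ((cand - t0) / grid.dt).astype(int), grid.n_steps - 1
    )
    accept = rng.uniform(0.0, lam_max, n_cand) < v[idx]
    times = np.unique(cand[accept])
    return SpikeTrain(times, (t0, t_end))


def rate_from_spikes(
    train: SpikeTrain, bin_width: float, smooth_sd: float = 0.0
) -> Signal:
    """Binned, optionally Gaussian-smoothed rate estimate.

    Counts per bin divided by the bin width; smoothing uses reflective
    boundaries so the total mass (integral of the estimate) stays within
    edge tolerance of the spike count.  The returned signal lives on a
    grid of bin centers.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    t0, t_end = train.span
    n_bins = int(round((t_end - t0) / bin_width))
    if n_bins < 2:
        raise ValueError(
            f"recording span {t_end - t0} too short for bin width {bin_width}"
        )
    edges = t0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(train.times, bins=edges)
    est = counts / bin_width
    if smooth_sd > 0:
        est = gaussian_filter1d(est, sigma=smooth_sd / bin_width, mode="reflect")
    grid = TimeGrid(t0=t0 + bin_width / 2.0, dt=bin_width, n_steps=n_bins)
    return Signal(grid, est)


def recording_from_traces(
    traces: TraceSet,
    rate_map: RateMap = RateMap(),
    seed: int = 0,
    bin_width: float = 0.5,
    smooth_sd: float = 1.0,
) -> Dict[str, Signal]:
    """Estimated-rate signal per node, emulating a unit recording.

    Composes the rate map, independent Poisson spike generation per unit
    (sub-seeds derived deterministically from ``seed``), and rate
    estimation; unit identifiers match :meth:`TraceSet.node_signals`.
    """
    units = traces.node_signals()
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(units))
    out: Dict[str, Signal] = {}
    for (name, activity), sub in zip(units.items(), sub_seeds):
        rate = rate_map.apply(activity)
        train = spikes_from_rate(rate, int(sub) & 0x7FFFFFFF)
        out[name] = rate_from_spikes(train, bin_width, smooth_sd)
    return out
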