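"""The experimental program as code: temporal signatures and control roles.

A comparator, a regulator, and a generator leave distinct temporal
fingerprints under two probe protocols.  After a step change in
*set-point*, the error node (C) responds only transiently — the loop is
wired to eliminate the error — while R and G settle at new sustained
levels.  After a step change in *load*, R sustains a change that opposes
the load while C and G are unsettled only transiently: the regulator
deals with unwanted signals so the generator is not distracted from
delivering the set-point.  This module quantifies those fingerprints
(:func:`signature_features`), assigns roles from paired probes
(:func:`classify_roles`), and estimates a regulator's integration window
from a pulse-duration sweep (:func:`estimate_integration_window`), the
in-silico analogue of varying how long a transmitter is applied.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np

from .circuit import CircuitSpec, Scenario, TraceSet, simulate
from .signals import Signal, StepSchedule, make_constant_profile, make_step_profile

__all__ = [
    "SignatureFeatures",
    "RoleAssignment",
    "RoleReport",
    "WindowEstimate",
    "signature_features",
    "classify_roles",
    "estimate_integration_window",
    "settling_time",
    "run_probe_protocol",
]

ROLES = ("comparator", "regulator", "generator", "unclassified")

#: absolute responsiveness floor for noiseless traces
_ABS_FLOOR = 1e-6
#: peak must exceed this multiple of the pre-window sd to count as responsive
_SD_MULT = 5.0


@dataclass(frozen=True)
class SignatureFeatures:
    """Transient-vs-sustained summary of one trace under one probe.

    ``transient_index = 1 - final_deviation / peak_deviation`` is 1 for a
    purely transient response (returns to baseline) and 0 for a purely
    sustained one; it is NaN when the trace is unresponsive (peak below
    the responsiveness threshold), rather than a guess.
    """

    baseline: float
    peak_deviation: float
    final_deviation: float
    transient_index: float
    responsive: bool
    pre_sd: float


def signature_features(
    trace: Signal,
    probe_onset: float,
    pre_fraction: float = 0.2,
    tail_fraction: float = 0.1,
) -> SignatureFeatures:
    """Baseline, peak and final deviations of a trace around a probe.

    The baseline is the mean over a pre-onset window spanning
    ``pre_fraction`` of the grid duration; the final level is the mean
    over the trailing ``tail_fraction``; the peak is the maximum
    absolute post-onset deviation from baseline.
    """
    grid = trace.grid
    if not 0 < pre_fraction < 1 or not 0 < tail_fraction < 1:
        raise ValueError("pre_fraction and tail_fraction must be in (0, 1)")
    i_on = grid.index_at(probe_onset)
    pre_span = pre_fraction * grid.duration
    i_pre = grid.index_at(max(grid.t0, probe_onset - pre_span))
    if i_on - i_pre < 1:
        raise ValueError(
            f"empty pre-onset window: probe onset {probe_onset} leaves no "
            f"samples before it"
        )
    n_tail = max(1, int(round(tail_fraction * grid.n_steps)))
    if grid.n_steps - n_tail < i_on:
        raise ValueError(
            f"tail window (last {n_tail} samples) overlaps the probe onset"
        )

    v = trace.values
    baseline = float(np.mean(v[i_pre:i_on]))
    pre_sd = float(np.std(v[i_pre:i_on]))
    dev = v[i_on:] - baseline
    peak = float(np.max(np.abs(dev)))
    final = float(abs(np.mean(v[-n_tail:]) - baseline))
    threshold = max(_SD_MULT * pre_sd, _ABS_FLOOR)
    responsive = peak > threshold
    ti = 1.0 - final / peak if responsive else math.nan
    return SignatureFeatures(
        baseline=baseline,
        peak_deviation=peak,
        final_deviation=final,
        transient_index=ti,
        responsive=responsive,
        pre_sd=pre_sd,
    )


@dataclass(frozen=True)
class RoleAssignment:
    role: str
    features_setpoint: SignatureFeatures
    features_load: SignatureFeatures
    reason: str = ""


@dataclass(frozen=True)
class RoleReport:
    """Per-unit features under both probes and the assigned control role."""

    assignments: Mapping[str, RoleAssignment]

    def roles(self) -> dict:
        return {unit: a.role for unit, a in self.assignments.items()}

    def to_frame(self):
        import pandas as pd

        rows = []
        for unit, a in self.assignments.items():
            rows.append(
                {
                    "unit": unit,
                    "role": a.role,
                    "transient_index_sp": a.features_setpoint.transient_index,
                    "transient_index_ld": a.features_load.transient_index,
                    "reason": a.reason,
                }
            )
        return pd.DataFrame(rows)


def classify_roles(
    units_setpoint: Mapping[str, Signal],
    units_load: Mapping[str, Signal],
    onset_setpoint: float,
    onset_load: float,
    theta: float = 0.5,
    pre_fraction: float = 0.2,
    tail_fraction: float = 0.1,
) -> RoleReport:
    """Assign a control role to each unit from its paired probe responses.

    A responsive unit is *sustained* under a probe iff its final
    deviation is at least ``theta`` times its peak deviation, else
    *transient*.  Rule table: sustained under both probes -> regulator;
    sustained under the set-point probe only -> generator; transient
    under both -> comparator; any other pattern -> unclassified (no
    guessing).
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    if set(units_setpoint) != set(units_load):
        missing = set(units_setpoint) ^ set(units_load)
        raise ValueError(f"unit sets differ between probes: {sorted(missing)}")

    assignments = {}
    for unit in units_setpoint:
        f_sp = signature_features(
            units_setpoint[unit], onset_setpoint, pre_fraction, tail_fraction
        )
        f_ld = signature_features(
            units_load[unit], onset_load, pre_fraction, tail_fraction
        )

        def sustained(f: SignatureFeatures) -> bool:
            return f.responsive and f.final_deviation >= theta * f.peak_deviation

        def transient(f: SignatureFeatures) -> bool:
            return f.responsive and f.final_deviation < theta * f.peak_deviation

        if not f_sp.responsive and not f_ld.responsive:
            role, reason = "unclassified", "unresponsive under both probes"
        elif sustained(f_sp) and sustained(f_ld):
            role, reason = "regulator", "sustained under both probes"
        elif sustained(f_sp) and transient(f_ld):
            role, reason = "generator", "sustained under set-point probe only"
        elif transient(f_sp) and transient(f_ld):
            role, reason = "comparator", "transient under both probes"
        else:
            role, reason = "unclassified", "pattern matches no role"
        assignments[unit] = RoleAssignment(role, f_sp, f_ld, reason)
    return RoleReport(assignments)


@dataclass(frozen=True)
class WindowEstimate:
    """Result of a pulse-duration sweep: the fitted window and a regime flag.

    ``regime`` is one of ``"estimated"`` (a plateau was observed and a
    window fitted), ``"lower_bound"`` (no plateau within the probed
    durations: the window is at least the longest duration) or
    ``"multiplier_like"`` (peaks are duration-independent, the
    fingerprint of a proportional block).
    """

    w_hat: float
    regime: str


def estimate_integration_window(
    durations: Sequence[float],
    peak_responses: Sequence[float],
    k: float,
    amplitude: float,
    n_grid: int = 200,
    flat_tol: float = 0.05,
) -> WindowEstimate:
    """Fit ``peak / (k*A) = min(T, w)`` to a pulse-duration sweep.

    An integrator's peak response to a pulse of amplitude ``A`` and
    duration ``T`` grows linearly with ``T`` until the window ``w`` is
    filled, then plateaus at ``k*A*w``.  The fit searches ``w`` over
    ``n_grid`` log-spaced points on the probed-duration hull; ties break
    toward the smaller window.
    """
    T = np.asarray(durations, dtype=float)
    peaks = np.asarray(peak_responses, dtype=float)
    if T.shape != peaks.shape:
        raise ValueError("durations and peak_responses must have equal length")
    if np.unique(T).size < 3:
        raise ValueError("need at least 3 distinct pulse durations")
    if np.max(T) / np.min(T) < 4:
        raise ValueError(
            f"durations must span at least a factor of 4, got "
            f"{np.min(T)}..{np.max(T)}"
        )
    if np.any(peaks < 0):
        raise ValueError("peak responses must be nonnegative")
    if not k > 0 or not amplitude > 0:
        raise ValueError("k and amplitude must be positive")

    p = peaks / (k * amplitude)
    scale = max(float(np.mean(p)), _ABS_FLOOR)
    if float(np.max(p) - np.min(p)) <= flat_tol * scale:
        return WindowEstimate(w_hat=math.nan, regime="multiplier_like")

    ws = np.geomspace(np.min(T), np.max(T), n_grid)
    sse = np.array([np.sum((p - np.minimum(T, w)) ** 2) for w in ws])
    best = int(np.argmin(sse))  # first minimum -> smaller w on ties
    if best == n_grid - 1:
        return WindowEstimate(w_hat=float(np.max(T)), regime="lower_bound")
    return WindowEstimate(w_hat=float(ws[best]), regime="estimated")


def settling_time(trace: Signal, target: float, tol: float) -> float:
    """First time after which the trace stays within ``tol`` of ``target``.

    Returned as time elapsed from the start of the trace's grid;
    ``math.inf`` if the trace never settles into the band.
    """
    if not tol > 0:
        raise ValueError(f"tol must be positive, got {tol}")
    outside = np.abs(trace.values - target) > tol
    if not outside.any():
        return 0.0
    last_bad = int(np.max(np.nonzero(outside)[0]))
    if last_bad == trace.grid.n_steps - 1:
        return math.inf
    return float((last_bad + 1) * trace.grid.dt)


def run_probe_protocol(
    circuit: CircuitSpec,
    grid=None,
    baseline_setpoint: float = 2.0,
    setpoint_level: float = 10.0,
    load_level: float = -20.0,
    onset: float = 30.0,
) -> Tuple[TraceSet, TraceSet]:
    """Run the paired probe protocols and return (set-point, load) traces.

    Probe 1 steps the set-point while the load stays zero; probe 2 holds
    the set-point and steps the load.  The default load step is negative
    (an inhibitory, sleep-pressure-like disturbance), which keeps the
    comparator's firing-rate mapping away from the zero-rate clip.  The
    default baseline and step amplitudes are sized for the Poisson SNR
    of the default rate map and smoothing in
    :mod:`arousalctl.recordings`: a transient of height ``h`` a.u.
    decays with time constant ``(1+g_c)/k`` t.u. and survives Gaussian
    smoothing at roughly half its height, the noise floor of the
    smoothed rate estimate is about ``sqrt(0.28 * rate)``, and — the
    binding constraint — the generator's dip under an inhibitory load
    is floor-limited by its baseline firing rate, so the baseline
    set-point supplies headroom and the load step is large enough that
    the silenced interval outlasts the smoothing kernel.
    """
    from .signals import TimeGrid

    if grid is None:
        grid = TimeGrid.from_horizon(100.0, dt=0.01)
    sp_step = make_step_profile(
        StepSchedule(baseline_setpoint, ((onset, setpoint_level),)), grid
    )
    zero = make_constant_profile(0.0, grid)
    const_sp = make_constant_profile(baseline_setpoint, grid)
    ld_step = make_step_profile(StepSchedule(0.0, ((onset, load_level),)), grid)
    traces_sp = simulate(circuit, Scenario(setpoint=sp_step, load=zero))
    traces_ld = simulate(circuit, Scenario(setpoint=const_sp, load=ld_step))
    return traces_sp, traces_ld
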