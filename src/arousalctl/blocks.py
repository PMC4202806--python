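"""The three control computations and the transmitter decay kernels.

The loop has three node types.  The *comparator* (hypothesized: orexin/
hypocretin neurons) subtracts the fed-back output from the desired
set-point, producing an error signal ``e = r - y``.  The *regulator*
(hypothesized: OXR2-expressing neurons such as histamine cells) turns the
error into a control signal; four regulator kinds are provided:

``proportional``
    A multiplier, ``u = k*e`` — no memory.
``window_integral``
    A moving-window integrator, ``u(t) = k * integral of e over the last
    w time units`` — the idealized integrator with a hard window ``w``.
``kernel_integral``
    Leaky integration of the error against a mixture of exponential decay
    kernels ``kappa(s) = sum_i p_i * exp(-lambda_i * s)`` with
    ``lambda_i = ln2 / h_i``.  Each component models a transmitter pool
    with half-life ``h_i``; by convention a two-component mixture has a
    long-lived "A" peptide and a short-lived "B" peptide, so the mixture
    fraction tunes the effective integration window.
``lowpass``
    A first-order filter ``tau * du/dt = k*e - u`` — the main competing
    interpretation of integrator-like electrophysiology; achieving small
    steady error with a low-pass regulator requires much more gain than
    integral feedback.

All kinds accept an optional derivative term ``k_d`` (control action on
the recent trend of the error) and optional output saturation.  The
*generator* (hypothesized: noradrenaline / locus-coeruleus neurons) is an
algebraic summing point: ``y = u + g_c*e + d``, where ``g_c`` is a direct
comparator-to-generator gain (zero in the basic loop topology).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import lfilter

from .signals import Signal, TimeGrid

__all__ = [
    "KernelSpec",
    "RegulatorSpec",
    "GeneratorSpec",
    "REGULATOR_KINDS",
    "comparator_value",
    "regulator_response",
    "generator_value",
    "effective_window",
    "dc_gain",
    "RegulatorState",
]

REGULATOR_KINDS = ("proportional", "window_integral", "kernel_integral", "lowpass")

LN2 = math.log(2.0)


@dataclass(frozen=True)
class KernelSpec:
    """Mixture-of-exponentials decay kernel, normalized so kappa(0) = 1.

    ``components`` is a tuple of ``(weight, half_life)`` pairs; weights
    are nonnegative and sum to one, half-lives are positive.  The decay
    rate of a component is ``lambda = ln2 / half_life``.
    """

    components: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        comps = tuple((float(p), float(h)) for p, h in self.components)
        if not comps:
            raise ValueError("kernel needs at least one component")
        if any(p < 0 for p, _ in comps):
            raise ValueError(f"kernel weights must be >= 0, got {comps}")
        if not math.isclose(sum(p for p, _ in comps), 1.0, abs_tol=1e-9):
            raise ValueError(
                f"kernel weights must sum to 1, got {sum(p for p, _ in comps)}"
            )
        if any(h <= 0 for _, h in comps):
            raise ValueError(f"kernel half-lives must be positive, got {comps}")
        object.__setattr__(self, "components", comps)

    @classmethod
    def from_mixture(
        cls, p_B: float, h_A: float = 20.0, h_B: float = 1.0
    ) -> "KernelSpec":
        """Two-component mixture: fraction ``p_B`` of the short-lived "B"
        peptide (half-life ``h_B``), the rest the long-lived "A" peptide."""
        if not 0 <= p_B <= 1:
            raise ValueError(f"p_B must be in [0, 1], got {p_B}")
        return cls(((1.0 - p_B, h_A), (p_B, h_B)))

    @property
    def weights(self) -> np.ndarray:
        return np.array([p for p, _ in self.components])

    @property
    def half_lives(self) -> np.ndarray:
        return np.array([h for _, h in self.components])

    @property
    def rates(self) -> np.ndarray:
        """Decay rates ``lambda_i = ln2 / h_i``."""
        return LN2 / self.half_lives

    def evaluate(self, s) -> np.ndarray:
        """kappa(s) = sum_i p_i exp(-lambda_i s)."""
        s = np.asarray(s, dtype=float)
        return np.sum(
            self.weights[:, None] * np.exp(-self.rates[:, None] * s[None, :]), axis=0
        ) if s.ndim else float(np.sum(self.weights * np.exp(-self.rates * s)))


def effective_window(kernel: KernelSpec) -> float:
    """Summary timescale of a kernel: w_eff = integral(kappa) / kappa(0).

    For a mixture of exponentials this is ``sum_i p_i / lambda_i`` — the
    mean effective lifetime of the transmitter mix.  It plays the role
    the hard window ``w`` plays for the moving-window integrator.
    """
    return float(np.sum(kernel.weights / kernel.rates))


@dataclass(frozen=True)
class RegulatorSpec:
    """Parameters of one regulator computation.

    Exactly the parameters belonging to ``kind`` may be set: ``w`` for
    ``window_integral``, ``tau`` for ``lowpass``, ``kernel`` for
    ``kernel_integral``; a mismatch is rejected.  ``k_d`` adds derivative
    action and ``saturation = (u_min, u_max)`` clips the output.
    """

    kind: str
    k: float = 1.0
    w: Optional[float] = None
    tau: Optional[float] = None
    kernel: Optional[KernelSpec] = None
    k_d: float = 0.0
    saturation: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in REGULATOR_KINDS:
            raise ValueError(
                f"unknown regulator kind '{self.kind}'; choose from {REGULATOR_KINDS}"
            )
        if not self.k > 0:
            raise ValueError(f"regulator gain k must be positive, got {self.k}")
        if self.k_d < 0:
            raise ValueError(f"derivative gain k_d must be >= 0, got {self.k_d}")
        needs = {"window_integral": "w", "lowpass": "tau", "kernel_integral": "kernel"}
        for kind, param in needs.items():
            val = getattr(self, param)
            if self.kind == kind and val is None:
                raise ValueError(f"regulator kind '{kind}' requires parameter '{param}'")
            if self.kind != kind and val is not None:
                raise ValueError(
                    f"parameter '{param}' is not valid for regulator kind '{self.kind}'"
                )
        if self.w is not None and not self.w > 0:
            raise ValueError(f"integration window w must be positive, got {self.w}")
        if self.tau is not None and not self.tau > 0:
            raise ValueError(f"time constant tau must be positive, got {self.tau}")
        if self.saturation is not None:
            lo, hi = self.saturation
            if not lo < hi:
                raise ValueError(
                    f"saturation bounds require u_min < u_max, got ({lo}, {hi})"
                )
            object.__setattr__(self, "saturation", (float(lo), float(hi)))

    @property
    def is_linear(self) -> bool:
        return self.saturation is None


@dataclass(frozen=True)
class GeneratorSpec:
    """Generator summing point; ``g_c`` is the direct C-to-G gain
    (0 in the basic loop, 1 by default in the feedforward topology)."""

    g_c: float = 1.0

    def __post_init__(self) -> None:
        if self.g_c < 0:
            raise ValueError(f"direct gain g_c must be >= 0, got {self.g_c}")


def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value}")
    return arr


def comparator_value(setpoint, feedback):
    """Error signal e = r - y (exact subtraction; scalars or arrays)."""
    r = _check_finite("setpoint", setpoint)
    y = _check_finite("feedback", feedback)
    out = r - y
    return float(out) if out.ndim == 0 else out


def generator_value(control, direct_error, load, spec: GeneratorSpec):
    """Generator output y = u + g_c*e + d (algebraic summing point)."""
    u = _check_finite("control", control)
    e = _check_finite("direct_error", direct_error)
    d = _check_finite("load", load)
    out = u + spec.g_c * e + d
    return float(out) if out.ndim == 0 else out


def dc_gain(spec: RegulatorSpec, horizon: Optional[float] = None) -> float:
    """Steady-state (DC) gain of a regulator on constant input.

    ``math.inf`` is returned for a window integrator whose window covers
    the whole run (``w >= horizon``), i.e. integration that never
    forgets within the simulated horizon.  Derivative action contributes
    nothing at DC.
    """
    if spec.kind == "proportional":
        return spec.k
    if spec.kind == "lowpass":
        return spec.k
    if spec.kind == "window_integral":
        if horizon is not None and spec.w >= horizon:
            return math.inf
        return spec.k * spec.w
    if spec.kind == "kernel_integral":
        return spec.k * effective_window(spec.kernel)
    raise AssertionError(spec.kind)


def regulator_response(spec: RegulatorSpec, error: Signal) -> Signal:
    """Open-loop regulator output for a given error signal.

    Discretization is current-sample-inclusive with step weight ``dt``
    (left-rectangle quadrature), so a window integrator with ``w == dt``
    is exactly a proportional block with gain ``k*dt``, and the kernel
    integrator reduces exactly to the window integrator as all
    half-lives grow without bound.
    """
    grid = error.grid
    dt = grid.dt
    e = error.values
    k = spec.k

    if spec.kind == "proportional":
        u = k * e
    elif spec.kind == "window_integral":
        if spec.w < dt:
            raise ValueError(
                f"integration window w={spec.w} must be >= grid dt={dt}"
            )
        m = max(1, int(round(spec.w / dt)))
        c = np.cumsum(e) * dt
        u = k * (c - np.concatenate([np.zeros(min(m, e.size)), c[:-m]])[: e.size])
    elif spec.kind == "kernel_integral":
        u = np.zeros_like(e)
        for p, lam in zip(spec.kernel.weights, spec.kernel.rates):
            # z_n = dt * sum_{j<=n} e_j exp(-lam*dt*(n-j))
            z = lfilter([dt], [1.0, -math.exp(-lam * dt)], e)
            u += p * z
        u *= k
    elif spec.kind == "lowpass":
        alpha = math.exp(-dt / spec.tau)
        u = lfilter([k * (1.0 - alpha)], [1.0, -alpha], e)
    else:  # pragma: no cover
        raise AssertionError(spec.kind)

    if spec.k_d > 0:
        u = u + spec.k_d * np.diff(e, prepend=0.0) / dt
    if spec.saturation is not None:
        u = np.clip(u, *spec.saturation)
    return Signal(grid, u)


class RegulatorState:
    """Stateful one-step regulator evaluator used by the closed-loop engine.

    State-bearing kinds contribute to the per-step summing-point solve
    through *lagged* state only (explicit scheme); the instantaneous
    algebraic gain ``k_inst`` is nonzero only for the proportional kind.
    This keeps the per-step fixed point scalar and reproduces the
    textbook discrete root locus (a basic integral loop is unstable iff
    ``k*dt >= 2``).  The derivative term uses the previous two regulator
    inputs, avoiding an algebraic loop.
    """

    def __init__(self, spec: RegulatorSpec, grid: TimeGrid):
        self.spec = spec
        self.dt = grid.dt
        self.k_inst = spec.k if spec.kind == "proportional" else 0.0
        self._e1 = 0.0  # previous regulator input
        self._e2 = 0.0  # the one before
        kind = spec.kind
        if kind == "window_integral":
            if spec.w < grid.dt:
                raise ValueError(
                    f"integration window w={spec.w} must be >= grid dt={grid.dt}"
                )
            m = max(1, int(round(spec.w / grid.dt)))
            # window covering the whole run never evicts: plain accumulator
            self._m = None if m >= grid.n_steps else m
            self._buf = None if self._m is None else np.zeros(self._m)
            self._ptr = 0
            self._sum = 0.0
        elif kind == "kernel_integral":
            self._z = np.zeros(len(spec.kernel.components))
            self._decay = np.exp(-spec.kernel.rates * grid.dt)
            self._weights = spec.kernel.weights
        elif kind == "lowpass":
            self._alpha = math.exp(-grid.dt / spec.tau)
            self._u = 0.0

    def state_output(self) -> float:
        """Lagged (state-determined) part of the control signal."""
        spec = self.spec
        kind = spec.kind
        if kind == "proportional":
            u = 0.0
        elif kind == "window_integral":
            u = spec.k * self._sum
        elif kind == "kernel_integral":
            u = spec.k * float(np.dot(self._weights, self._z))
        else:  # lowpass
            u = self._u
        if spec.k_d > 0:
            u += spec.k_d * (self._e1 - self._e2) / self.dt
        return u

    def update(self, reg_input: float) -> None:
        """Advance the state with this step's regulator input."""
        spec = self.spec
        kind = spec.kind
        if kind == "window_integral":
            inc = reg_input * self.dt
            if self._m is None:
                self._sum += inc
            else:
                self._sum += inc - self._buf[self._ptr]
                self._buf[self._ptr] = inc
                self._ptr = (self._ptr + 1) % self._m
        elif kind == "kernel_integral":
            self._z = self._z * self._decay + reg_input * self.dt
        elif kind == "lowpass":
            a = self._alpha
            self._u = a * self._u + spec.k * (1.0 - a) * reg_input
        if spec.k_d > 0:
            self._e2 = self._e1
            self._e1 = reg_input
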