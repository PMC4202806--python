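# Methods

## Model

The loop couples three rate-level computations on a uniform time grid
(dimensionless time units, t.u.; activity in arbitrary units, a.u.).
The comparator is an exact subtraction `e = r − y`. The generator is an
algebraic summing point `y = u + g_c·e + d`, where `g_c` is a direct
comparator→generator gain: `g_c = 0` in the *basic* topology,
`g_c = 1` by default in the *feedforward* topology, which mirrors orexin
cells synapsing onto both putative regulators (histamine) and putative
generators (noradrenaline). Neither C nor G has intrinsic dynamics —
the model idealizes these neurons as algebraic summing points.

Four regulator computations cover the hypothesis space:

| kind | computation | memory |
|---|---|---|
| `proportional` | `u = k·e` | none (a multiplier) |
| `window_integral` | `u = k·∫_{t−w}^{t} e ds` | hard window `w` |
| `kernel_integral` | `u = k·∫ κ(s)·e(t−s) ds` | transmitter decay mixture |
| `lowpass` | `τ·du/dt = k·e − u` | first-order filter |

The kernel is a normalized mixture of exponentials
`κ(s) = Σᵢ pᵢ·exp(−λᵢ s)`, `κ(0) = 1`, `λᵢ = ln2/hᵢ`, each component a
transmitter pool with half-life `hᵢ`. Its **effective window** is
defined here as `w_eff = ∫κ/κ(0) = Σᵢ pᵢ/λᵢ` — the mean effective
lifetime of the mix. This definition is a package choice: the hard
window `w` has an unambiguous meaning, a leaky kernel does not, and
`∫κ/κ(0)` is the unique first-order summary that makes the two agree
for near-first-order kernels. Normalizing `κ(0) = 1` keeps `k` the sole
gain parameter, so a longer-lived mixture has a *larger* DC gain
(`k·w_eff`) at identical `k` — deliberately preserving the physiological
trade-off that more persistent transmitter accumulates more.

An optional derivative term `k_d·de/dt` (control on the recent error
trend, as glutamate co-release might provide) and optional output
saturation `(u_min, u_max)` (receptor saturation during sustained
firing) extend every kind.

Two-component mixtures are parameterized as `(p_B, h_A, h_B)` with
`p_A = 1 − p_B`; defaults `h_A = 20`, `h_B = 1` t.u. are free parameters
standing in for a hard-to-degrade "A" peptide and a labile "B" peptide —
no measured half-lives exist at this level of abstraction.

## Discretization and the engine

Fixed step `dt = 0.01` t.u. (default), horizon 100 t.u. unless stated;
all pre-history is zero (system at rest).

**Open-loop responses** (`regulator_response`) use left-rectangle
quadrature including the current sample: `u_n` depends on `e_0..e_n`.
Consequences that double as unit checks: a window of one sample equals a
proportional block with gain `k·dt` exactly, and the kernel integrator
reduces exactly to the window integrator as all half-lives grow beyond
the horizon. Kernel states update per component as
`z ← z·exp(−λ·dt) + e·dt` (O(components) per step); the low-pass filter
uses the exact exponential update `u ← α·u + k(1−α)·e`, `α = exp(−dt/τ)`.
The moving window is a running sum with eviction (O(1) per step).

**The closed-loop engine** solves the two summing points *exactly* at
every step as a scalar linear fixed point over the instantaneous paths:
state-bearing regulator kinds contribute through lagged state only
(explicit scheme, instantaneous gain `k_inst = 0`), the proportional
kind through `k_inst = k`. For the default injection point the solve is
`e_n = (r_n − u_state − d_n)/(1 + g_c + k_inst)`; the output is then
assigned as `y_n = r_n − e_n`, which makes the comparator identity
`e + y = r` hold to the last bit. When saturation clips the control
signal the remaining fixed point is re-solved with the clipped constant,
so the identity survives nonlinearity. A `delayed` engine mode that
breaks the loop with a unit delay exists for comparison; the open-loop
and closed-loop conventions differ by one sample (O(dt)), which is
invisible at default `dt`.

The load can enter at the generator (default — the final summing
point), at the comparator, or at the regulator input. A load injected
at the comparator is processed as if it were demand: the steady output
becomes `r + d`, the loop's known catastrophic weak point.

**Stability.** `check_stability` builds the homogeneous linear update
map of the engine recursion (ring-buffer entries, kernel states, filter
state, derivative lags) and reports its spectral radius: dense
eigenvalues up to dimension 800, power iteration beyond, and an
empirical probe simulation (flagged heuristic) for saturated
configurations. The basic integral loop has radius `|1 − k·dt/(1+g_c)|`,
hence the classic discrete instability at `k·dt ≥ 2`. `simulate` refuses
configurations flagged unstable unless overridden and additionally
guards against divergence (`|y| > 10⁶·max(|r|,|d|,1)`) at run time.

**DC oracle.** `dc_solve` returns the algebraic steady state for every
linear configuration, treating an over-horizon window (`w ≥ horizon`)
as infinite DC gain (perfect integral action: zero steady regulator
input). It is the independent surface against which the engine is
validated: across 2 topologies × 4 kinds × 3 gains × 3 loads the
simulated tail means (last 10% of a 200 t.u. run) agree with `dc_solve`
to better than `max(10⁻³, 2·dt)` — measured worst deviation ≈ 8×10⁻⁵.

## Diagnostics

`signature_features` summarizes one trace around one probe: baseline =
mean of the pre-onset window (20% of the horizon before onset), peak =
max |deviation| after onset, final = |tail mean − baseline| (tail =
last 10%), and `transient_index = 1 − final/peak`. A unit is
*responsive* only if its peak exceeds `max(5·pre-sd, 10⁻⁶)`; features of
unresponsive traces are flagged rather than guessed.

`classify_roles` applies the signature rule table at threshold
`θ = 0.5` (sustained iff `final ≥ θ·peak`): sustained under both
set-point and load probes → regulator; sustained under set-point only →
generator; transient under both → comparator; anything else →
unclassified. On noiseless probes the assignment is correct for every
stable integral configuration and every `θ ∈ [0.3, 0.7]` — the
classification is not knife-edge at the default.

The bundled probe protocol holds a constant baseline set-point and
steps either the set-point or the load at t = 30 on a 100 t.u.
horizon. Default amplitudes (baseline set-point 2, set-point step to
10, load step to −20) are sized for the Poisson SNR
of the synthetic recording chain: a transient of height `h` a.u. decays
with time constant `(1+g_c)/k` and survives the default smoothing at
roughly half height, the smoothed-rate noise floor is ≈ `√(0.28·rate)`,
and — the binding constraint — the generator's dip under an inhibitory
load is floor-limited at zero firing rate, so the baseline set-point
must supply rate headroom and the load step must silence the unit for
longer than the smoothing kernel. The load probe is negative
(an inhibitory, sleep-pressure-like disturbance); a positive load would
drive the comparator's low baseline rate into the zero-rate clip
instead.

`estimate_integration_window` fits `peak/(k·A) = min(T, w)` to a
pulse-duration sweep by least squares over 200 log-spaced candidate
windows on the probed-duration hull, ties toward the smaller window.
Flat peak profiles (range ≤ 5% of mean) are flagged `multiplier_like`
(proportional fingerprint — also the honest answer for a window shorter
than every probed duration); a best fit at the hull's upper edge is
flagged `lower_bound` with `ŵ = max duration`. With five octave-spaced
durations and 5% response noise the estimate lands within ±10% of the
true window in ≈99 of 100 trials.

`settling_time` returns the first time after which a trace stays within
a band for the remainder of the horizon (∞ sentinel if never). In the
half-life analyses settling is measured relative to each loop's *own*
post-reversal steady state (the standard control definition): measured
against the raw set-point, a short-window loop never enters the band at
all — its finite DC gain leaves a standing offset, which is the
proportional-like failure mode rather than a settling-speed ordering.

## Synthetic recordings

The measurement chain emulating unit recordings is: affine rate map
`rate = max(0, r0 + gain·activity)` (defaults r0 = 5, gain = 10
events/t.u.; clipping fraction is logged because heavy clipping distorts
signatures) → inhomogeneous Poisson spikes by thinning against the rate
maximum (exact for the piecewise-constant rates used; chosen over
time-rescaling for that exactness) → binned counts (bin 0.5 t.u.) with
Gaussian smoothing (sd 1.0 t.u., reflective boundaries so mass is
conserved). Sub-seeds per unit derive deterministically from one master
seed. What this emulates: Poisson sampling noise, rate floors, and
estimator smoothing. What it does not: refractoriness, bursting,
spike-sorting errors, nonstationary baselines — so passing tests show
robustness to counting noise, not to every artifact of in vivo data.
Through this chain the role classifier recovers all three roles in
≥ 19/20 seeds at defaults; accuracy degrades as the rate-map gain (SNR)
shrinks, as it must.

## Half-life tuning analysis

Tracking performance is the integrated squared error (ISE; IAE
available) of the loop output against a square-wave set-point
(levels 0.5/1.5), excluding one half-period of burn-in so the score
reflects steady cyclic behavior. Environments default to
`P_fast = 4`, `P_slow = 100` t.u. with horizon `3P` — the minimum the
spec of a cyclic score permits — chosen to bracket the default
`w_eff` range (≈1.4–29 t.u.).

Verified regime behavior: (a) with vanishing half-life (`w_eff = 0.1`)
the loop's square-wave plateau error matches the proportional
controller of gain `k·w_eff` within 0.5% — "too-short lifespan degrades
integral to proportional control"; (b) settling after a set-point
reversal grows monotonically with `w_eff` (1.04 → 2.15 → 2.59 t.u. for
`w_eff` = 1, 5, 20) — "too-long lifespan leaves control signals
lingering"; (c) the mixture sweep holds `k` fixed across the `p_B` grid
(no DC renormalization), so with the default parameterization the
higher DC gain of long-lived mixtures dominates both environments and
the ISE-optimal `p_B` is 0.0 for fast *and* slow environments — the
fast-environment optimum is never *below* the slow one, but at these
defaults the directional shift toward short-lived transmitter in fast
environments appears as a weak ordering, not a strict one. This is a
property of the fixed-`k`, `κ(0)=1` parameterization, reported as
measured; matched-DC-gain comparisons are the natural sensitivity
analysis and the near-first-order equivalence test (two kernels with
equal `w_eff` and `k` tracking within 1%) holds only for mildly
heterogeneous mixtures — strongly bimodal mixtures (h_A/h_B = 12)
deviate by ~29%.

## Numerical choices and limitations

- Step profiles are left-closed (the onset sample carries the new
  level); event times snap to the grid within 10⁻⁹·dt.
- Noise injection is additive Gaussian white noise with a mandatory
  seed; every stochastic call in the package is reproducible.
- The staircase formula `start + inc·floor((t−t0)/interval)` starts a
  new tread exactly at multiples of the interval, so analyses that need
  "the last tread held to the end" end the grid one sample early.
- Tie-breaks: window fits toward the smaller window; mixture optima
  toward larger `p_B` (the shorter window), flagged when tied.
- Degenerate inputs are rejected with named errors (empty pre-windows,
  onsets outside the grid, `w < dt`, unknown config keys) rather than
  patched silently.
- Rate-level blocks only: no conductance-based or spiking dynamics in
  the loop itself, no plasticity, no sleep-side dynamics (sleep
  pressure enters only as load/noise), no multi-regulator redundancy,
  and no inference of circuit topology beyond the three-role
  assignment.
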