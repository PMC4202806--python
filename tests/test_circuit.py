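"""Closed-loop engine against the analytic steady-state oracle."""
import numpy as np
import pytest

from arousalctl import (
    CircuitSpec,
    GeneratorSpec,
    RegulatorSpec,
    Scenario,
    SimulationDiverged,
    StepSchedule,
    TimeGrid,
    UnstableCircuitError,
    check_stability,
    dc_solve,
    make_constant_profile,
    make_staircase_profile,
    make_step_profile,
    simulate,
)
from conftest import make_regulator


def constant_scenario(grid, r=1.0, d=0.0):
    return Scenario(
        setpoint=make_constant_profile(r, grid),
        load=make_constant_profile(d, grid),
    )


class TestCircuitSpec:
    def test_basic_topology_forces_zero_direct_gain(self):
        with pytest.raises(ValueError, match="g_c = 0"):
            CircuitSpec("basic", generator=GeneratorSpec(1.0))

    def test_feedforward_requires_direct_gain(self):
        with pytest.raises(ValueError, match="g_c > 0"):
            CircuitSpec("feedforward", generator=GeneratorSpec(0.0))

    def test_default_generator_follows_topology(self):
        assert CircuitSpec("basic").g_c == 0.0
        assert CircuitSpec("feedforward").g_c == 1.0

    def test_scenario_requires_shared_grid(self, grid, short_grid):
        with pytest.raises(ValueError, match="same time grid"):
            Scenario(
                make_constant_profile(1.0, grid),
                make_constant_profile(0.0, short_grid),
            )


class TestDcSolve:
    def test_basic_proportional_halves_the_setpoint(self):
        c = CircuitSpec("basic", regulator=RegulatorSpec("proportional", k=1.0))
        assert dc_solve(c, 1.0, 0.0) == pytest.approx((0.5, 0.5, 0.5))

    def test_basic_integral_annihilates_constant_load(self):
        c = CircuitSpec(
            "basic", regulator=RegulatorSpec("window_integral", k=1.0, w=200.0)
        )
        e, u, y = dc_solve(c, 1.0, 0.7, horizon=100.0)
        assert (e, u, y) == pytest.approx((0.0, 0.3, 1.0))

    def test_feedforward_proportional_closed_form(self):
        c = CircuitSpec("feedforward", regulator=RegulatorSpec("proportional", k=1.0))
        e, u, y = dc_solve(c, 1.0, 0.0)
        assert y == pytest.approx(2.0 / 3.0)
        assert e == pytest.approx(1.0 / 3.0)

    def test_load_at_comparator_masquerades_as_setpoint(self):
        c = CircuitSpec(
            "basic",
            regulator=RegulatorSpec("window_integral", k=1.0, w=200.0),
            load_injection="at_comparator",
        )
        e, u, y = dc_solve(c, 1.0, 0.3, horizon=100.0)
        assert y == pytest.approx(1.3)  # the loop treats the load as demand

    def test_rejects_nonlinear_spec(self):
        c = CircuitSpec(
            "basic",
            regulator=RegulatorSpec("proportional", k=1.0, saturation=(-1, 1)),
        )
        with pytest.raises(ValueError, match="linear"):
            dc_solve(c, 1.0, 0.0)


class TestSimulateExamples:
    def test_integral_loop_tracks_setpoint_step(self, grid, integral_circuit):
        sp = make_step_profile(StepSchedule(0.0, ((10.0, 1.0),)), grid)
        traces = simulate(
            integral_circuit, Scenario(sp, make_constant_profile(0.0, grid))
        )
        assert abs(traces.output.values[-1] - 1.0) < 1e-3
        assert abs(traces.error.values[-1]) < 1e-3

    def test_proportional_loop_shows_load_offset(self, grid):
        c = CircuitSpec("basic", regulator=RegulatorSpec("proportional", k=1.0))
        ld = make_step_profile(StepSchedule(0.0, ((50.0, 0.5),)), grid)
        traces = simulate(c, Scenario(make_constant_profile(1.0, grid), ld))
        assert traces.output.values[-1] == pytest.approx(0.75, abs=1e-9)
        assert traces.error.values[-1] == pytest.approx(0.25, abs=1e-9)

    def test_feedforward_integral_rejects_load(self, grid, feedforward_integral_circuit):
        ld = make_step_profile(StepSchedule(0.0, ((50.0, 0.4),)), grid)
        traces = simulate(
            feedforward_integral_circuit,
            Scenario(make_constant_profile(1.0, grid), ld),
        )
        assert abs(traces.error.values[-1]) < 1e-3
        assert traces.control.values[-1] == pytest.approx(0.6, abs=1e-3)
        assert traces.output.values[-1] == pytest.approx(1.0, abs=1e-3)

    def test_staircase_load_integral_recovers_proportional_drifts(self, grid):
        """Escalating opposing disturbance: the integral loop re-zeros its
        output before each next tread while the proportional loop's output
        deviation keeps growing."""
        ld = make_staircase_profile(0.0, -0.2, 20.0, grid)
        sp = make_constant_profile(1.0, grid)
        ci = CircuitSpec(
            "basic", regulator=RegulatorSpec("window_integral", k=1.0, w=200.0)
        )
        cp = CircuitSpec("basic", regulator=RegulatorSpec("proportional", k=1.0))
        ti = simulate(ci, Scenario(sp, ld))
        tp = simulate(cp, Scenario(sp, ld))
        # sample just before each tread change
        for t_check, d_level in [(39.9, -0.2), (59.9, -0.4), (79.9, -0.6), (99.9, -0.8)]:
            i = grid.index_at(t_check)
            assert abs(ti.output.values[i] - 1.0) < 1e-2
            expected = dc_solve(cp, 1.0, d_level).error
            assert tp.error.values[i] == pytest.approx(expected, abs=1e-9)
        prop_errors = [tp.error.values[grid.index_at(t)] for t in (39.9, 59.9, 99.9)]
        assert prop_errors[0] < prop_errors[1] < prop_errors[2]

    def test_comparator_conservation_to_machine_precision(self, grid):
        rng = np.random.default_rng(9)
        sp = make_constant_profile(1.0, grid).with_values(
            1.0 + 0.1 * rng.standard_normal(grid.n_steps)
        )
        ld = make_constant_profile(0.0, grid).with_values(
            0.2 * rng.standard_normal(grid.n_steps)
        )
        for kind in ("proportional", "window_integral", "kernel_integral", "lowpass"):
            c = CircuitSpec("feedforward", regulator=make_regulator(kind))
            tr = simulate(c, Scenario(sp, ld))
            # machine precision: at most a couple of ulps on O(1) values
            assert np.max(
                np.abs(tr.error.values + tr.output.values - sp.values)
            ) <= 5e-16

    def test_delayed_engine_mode_agrees_at_steady_state(self, grid, integral_circuit):
        sc = constant_scenario(grid, r=1.0, d=0.3)
        exact = simulate(integral_circuit, sc, engine_mode="exact")
        delayed = simulate(integral_circuit, sc, engine_mode="delayed")
        assert delayed.output.values[-1] == pytest.approx(
            exact.output.values[-1], abs=1e-6
        )


class TestOracleAgreement:
    @pytest.mark.parametrize("topology", ["basic", "feedforward"])
    @pytest.mark.parametrize(
        "kind", ["proportional", "window_integral", "kernel_integral", "lowpass"]
    )
    def test_tail_means_match_dc_solve(self, topology, kind):
        """Simulated tail means equal the algebraic fixed point for every
        linear configuration (spot grid; the full grid runs in acceptance)."""
        grid = TimeGrid.from_horizon(200.0, dt=0.01)
        tol = max(1e-3, 2 * grid.dt)
        for k in (0.5, 2.0):
            for d in (0.0, -0.5):
                c = CircuitSpec(topology, regulator=make_regulator(kind, k=k))
                tr = simulate(c, constant_scenario(grid, 1.0, d))
                dc = dc_solve(c, 1.0, d, horizon=grid.duration)
                assert tr.error.tail_mean() == pytest.approx(dc.error, abs=tol)
                assert tr.control.tail_mean() == pytest.approx(dc.control, abs=tol)
                assert tr.output.tail_mean() == pytest.approx(dc.output, abs=tol)

    def test_integral_error_elimination_for_any_bounded_load(self, grid):
        c = CircuitSpec(
            "basic", regulator=RegulatorSpec("window_integral", k=1.0, w=200.0)
        )
        for d in (-1.0, -0.3, 0.6, 1.0):
            tr = simulate(c, constant_scenario(grid, 1.0, d))
            assert abs(tr.error.values[-1]) < 1e-3

    def test_regulator_protects_generator_from_load_step(self, grid, integral_circuit):
        ld = make_step_profile(StepSchedule(0.0, ((30.0, 0.5),)), grid)
        tr = simulate(integral_circuit, Scenario(make_constant_profile(1.0, grid), ld))
        i_on = grid.index_at(30.0)
        peak_dev = np.max(np.abs(tr.output.values[i_on:] - 1.0))
        assert 0 < peak_dev < 1.0  # finite transient
        assert abs(tr.output.values[-1] - 1.0) < 1e-3
        assert tr.control.values[-1] - tr.control.values[i_on - 1] == pytest.approx(
            -0.5, abs=1e-3
        )

    def test_proportional_error_strictly_decreases_with_gain(self):
        errors = [
            abs(
                dc_solve(
                    CircuitSpec("basic", regulator=RegulatorSpec("proportional", k=k)),
                    1.0,
                    0.0,
                ).error
            )
            for k in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a > b for a, b in zip(errors, errors[1:]))


class TestStability:
    def test_integral_loop_stable_at_default_step(self, grid):
        c = CircuitSpec(
            "basic", regulator=RegulatorSpec("window_integral", k=1.0, w=1000.0)
        )
        rep = check_stability(c, grid)
        assert rep.stable and rep.spectral_radius < 1.0
        assert rep.spectral_radius == pytest.approx(1.0 - 1.0 * grid.dt)

    def test_proportional_loop_memoryless_stable(self, grid):
        c = CircuitSpec("basic", regulator=RegulatorSpec("proportional", k=50.0))
        rep = check_stability(c, grid)
        assert rep.stable and rep.spectral_radius == 0.0

    def test_integral_loop_unstable_when_k_dt_reaches_two(self):
        g = TimeGrid.from_horizon(10.0, dt=2.5)  # k*dt = 2.5 >= 2
        c = CircuitSpec(
            "basic", regulator=RegulatorSpec("window_integral", k=1.0, w=100.0)
        )
        rep = check_stability(c, g)
        assert not rep.stable and rep.spectral_radius >= 1.0

    def test_simulate_refuses_unstable_unless_overridden(self):
        g = TimeGrid.from_horizon(250.0, dt=2.5)
        c = CircuitSpec(
            "basic", regulator=RegulatorSpec("window_integral", k=1.0, w=100.0)
        )
        with pytest.raises(UnstableCircuitError):
            simulate(c, constant_scenario(g))
        with pytest.raises(SimulationDiverged, match="unstable"):
            simulate(c, constant_scenario(g), check=False)

    def test_finite_window_loop_analyzed_via_companion_map(self):
        g = TimeGrid.from_horizon(50.0, dt=0.1)
        c = CircuitSpec(
            "basic", regulator=RegulatorSpec("window_integral", k=1.0, w=3.0)
        )
        rep = check_stability(c, g)
        assert rep.stable and 0 < rep.spectral_radius < 1.0

    def test_nonlinear_spec_falls_back_to_heuristic_probe(self, grid):
        c = CircuitSpec(
            "basic",
            regulator=RegulatorSpec(
                "window_integral", k=1.0, w=200.0, saturation=(-5.0, 5.0)
            ),
        )
        rep = check_stability(c, grid)
        assert rep.heuristic and rep.stable


class TestSaturation:
    def test_saturated_control_limits_disturbance_rejection(self, grid):
        c = CircuitSpec(
            "basic",
            regulator=RegulatorSpec(
                "window_integral", k=1.0, w=200.0, saturation=(-0.2, 0.2)
            ),
        )
        tr = simulate(c, constant_scenario(grid, 1.0, -0.6), check=False)
        assert np.max(tr.control.values) <= 0.2 + 1e-12
        # control pinned at the rail: output settles at u_max + d, not r
        assert tr.output.values[-1] == pytest.approx(-0.4, abs=1e-9)
        # comparator identity still exact under clipping
        np.testing.assert_array_equal(
            tr.error.values + tr.output.values, tr.setpoint.values
        )
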