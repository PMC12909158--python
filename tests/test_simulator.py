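import numpy as np
import pytest

from evlpsim.parameters import default_config
from evlpsim.simulator import (
    ConvergenceError,
    InputSchedule,
    SimulationError,
    SolverSettings,
    StateVector,
    _integrate_cycle,
    _segment_rhs,
    resample_nearest,
    rhs,
    run_cycle_means,
    run_static_scenarios,
    run_to_steady_state,
    simulate,
)
from evlpsim.ventilator import VentilatorWaveform


class TestRhs:
    def test_scalar_closure_matches_compositional_rhs(self, config):
        """The integrator's optimized closure and the readable composition of
        the module-level operations must agree to machine precision."""
        rng = np.random.default_rng(1)
        clinical = config.clinical
        wf = VentilatorWaveform.from_clinical(clinical)
        for _ in range(50):
            y = np.array([
                rng.uniform(5, 13),      # p_a
                rng.uniform(0.05, 0.9),  # f_a_o2
                rng.uniform(0.0, 0.08),  # f_a_co2
                rng.uniform(20, 500),    # p_c_o2
                rng.uniform(5, 60),      # p_c_co2
                rng.uniform(0.001, 0.03),  # z
                rng.uniform(0.0, 0.6),   # v_a
                rng.uniform(0.0, 0.4),   # v_cum
                0.0, 0.0,
            ])
            t = rng.uniform(0, wf.t_cyc)
            inspiring = (t % wf.t_cyc) <= wf.t_insp
            end_exp = (float(y[1]), float(y[2]))
            from evlpsim.gas_exchange import breath_mixed_fractions

            fd = breath_mixed_fractions(
                clinical.vt, config.intrinsic.v_d, clinical.fio2,
                config.constants.fico2, *end_exp,
            )
            f = _segment_rhs(config, clinical, wf, inspiring, *fd)
            got = np.array(f(t % wf.t_cyc, y))[:8]
            want = rhs(t, y, config, end_exp_fractions=end_exp)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-15)

    def test_finite_difference_consistency(self, config, default_steady):
        """rhs matches a forward difference of a tiny integration step."""
        state, _ = default_steady
        y0 = state.as_array(config.clinical)
        deriv = rhs(0.5, y0, config)
        dt = 1e-7
        from scipy.integrate import solve_ivp

        wf = VentilatorWaveform.from_clinical(config.clinical)
        from evlpsim.gas_exchange import breath_mixed_fractions

        fd = breath_mixed_fractions(
            config.clinical.vt, config.intrinsic.v_d, config.clinical.fio2,
            config.constants.fico2, float(y0[1]), float(y0[2]),
        )
        f = _segment_rhs(config, config.clinical, wf, True, *fd)
        sol = solve_ivp(f, (0.5, 0.5 + dt), y0, rtol=1e-12, atol=1e-12)
        fd_deriv = (sol.y[:8, -1] - y0[:8]) / dt
        np.testing.assert_allclose(fd_deriv, deriv, rtol=1e-4, atol=1e-10)

    def test_cycle_periodicity(self, config):
        y = StateVector().as_array(config.clinical)
        a = rhs(1.0, y, config)
        b = rhs(1.0 + 9.0, y, config)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_nonfinite_state_raises(self, config):
        y = StateVector().as_array(config.clinical)
        y[0] = np.nan
        with pytest.raises(SimulationError):
            rhs(0.0, y, config)


class TestInputSchedule:
    def test_step(self, config):
        sched = InputSchedule.step("fio2", 180.0, 1.0)
        assert sched.clinical_at(0.0, config.clinical).fio2 == 0.21
        assert sched.clinical_at(180.0, config.clinical).fio2 == 1.0
        assert sched.clinical_at(500.0, config.clinical).fio2 == 1.0

    def test_non_decreasing_times_enforced(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            InputSchedule({"fio2": [(10.0, 1.0), (5.0, 0.21)]})

    def test_multiple_fields(self, config):
        sched = InputSchedule({"fio2": [(0.0, 0.3)], "peep": [(9.0, 8.0)]})
        clin = sched.clinical_at(10.0, config.clinical)
        assert clin.fio2 == 0.3
        assert clin.peep == 8.0


class TestSimulate:
    def test_output_grid_is_100hz(self, config, default_steady):
        state, _ = default_steady
        result = simulate(config, 5.0, initial=state)
        assert result.time[0] == 0.0
        np.testing.assert_allclose(np.diff(result.time), 0.01, atol=1e-9)
        assert result.time.size == 501

    def test_outputs_finite_and_within_physical_bounds(self, config, default_steady):
        state, _ = default_steady
        result = simulate(config, 30.0, initial=state)
        for name in ("f_a_o2", "f_a_co2"):
            assert np.all(result.states[name] >= 0.0)
            assert np.all(result.states[name] <= 1.0)
        assert np.all(result.states["f_a_o2"] + result.states["f_a_co2"] <= 1.0)
        for name in ("p_c_o2", "p_c_co2", "z"):
            assert np.all(result.states[name] >= 0.0)
        assert np.all(np.isfinite(result.p_la_o2))
        assert np.all(np.isfinite(result.p_la_co2))

    def test_cycle_resolved_oscillation(self, config, default_steady):
        """P_LA_O2 rises during inspiration and falls during expiration."""
        state, _ = default_steady
        result = simulate(config, 9.0, initial=state)
        t = result.time
        o2 = result.p_la_o2
        # allow a short diffusion lag after the phase switch
        insp = (t >= 1.0) & (t <= 3.0)
        exp = (t >= 5.0) & (t <= 8.0)
        assert np.mean(np.diff(o2[insp])) > 0
        assert np.mean(np.diff(o2[exp])) < 0

    def test_shunt_dominated_mixing(self, fast_settings):
        cfg = default_config().with_intrinsic(f_sh=0.95, f_ds=0.04)
        state, means = run_to_steady_state(cfg, settings=fast_settings)
        result = simulate(cfg, 9.0, initial=state, settings=fast_settings)
        p_c_mean = float(np.mean(result.states["p_c_o2"]))
        expected = 0.95 * cfg.clinical.p_pa_o2 + 0.05 * p_c_mean
        assert means["p_la_o2"] == pytest.approx(expected, abs=5.0)

    def test_volume_pressure_invariant(self, config, default_steady):
        """The mechanics pair conserves V_A - C_stat * P_A along the trajectory."""
        state, _ = default_steady
        result = simulate(config, 9.0, initial=state)
        const = result.states["v_a"] - config.clinical.c_stat * result.states["p_a"]
        assert float(np.std(const)) < 1e-6

    def test_tolerance_convergence(self, config, default_steady):
        """Tightening the tolerance leaves cycle-mean P_LA_O2 unchanged."""
        state, _ = default_steady
        means = {}
        for tol in (1e-7, 1e-9):
            _, _, o2, _ = run_cycle_means(
                config, 9.0, initial=state,
                settings=SolverSettings(rtol=tol, atol=tol),
            )
            means[tol] = o2[0]
        assert abs(means[1e-7] - means[1e-9]) < 0.01

    def test_invalid_duration(self, config):
        with pytest.raises(ValueError):
            simulate(config, 0.0)

    def test_invalid_config_rejected(self, config):
        with pytest.raises(ValueError, match="fio2"):
            simulate(config.with_clinical(fio2=1.5), 1.0)


class TestSteadyState:
    def test_defaults_reproduce_reported_outputs(self, default_steady):
        """Cycle-mean steady outputs at defaults land in the reported bands."""
        _, means = default_steady
        assert means["p_la_o2"] == pytest.approx(122.5, abs=10.0)
        assert means["p_la_co2"] == pytest.approx(24.6, abs=4.0)

    def test_idempotence(self, config, default_steady):
        state, means = default_steady
        state2, means2 = run_to_steady_state(config, initial=state)
        assert means2["n_cycles"] <= 2
        assert means2["p_la_o2"] == pytest.approx(means["p_la_o2"], abs=0.1)

    @pytest.mark.parametrize("field,scale", [
        ("p_a", 1.2), ("f_a_o2", 0.8), ("f_a_co2", 1.2),
        ("p_c_o2", 0.8), ("p_c_co2", 1.2), ("z", 0.8),
    ])
    def test_initial_condition_independence(self, config, fast_settings,
                                            field, scale):
        _, reference = run_to_steady_state(
            config, settings=fast_settings, steady_tol=0.01
        )
        init = StateVector()
        setattr(init, field, getattr(init, field) * scale)
        _, perturbed = run_to_steady_state(
            config, initial=init, settings=fast_settings, steady_tol=0.01
        )
        assert perturbed["p_la_o2"] == pytest.approx(reference["p_la_o2"], abs=0.1)
        assert perturbed["p_la_co2"] == pytest.approx(reference["p_la_co2"], abs=0.1)

    def test_nonconvergence_error(self, config):
        with pytest.raises(ConvergenceError, match="steady state"):
            run_to_steady_state(config, cap=20.0)

    def test_solver_independence(self, config, default_steady):
        """Cycle means from the adaptive solver match a fixed-step RK4
        reference over one cycle from the same converged state."""
        state, _ = default_steady
        clinical = config.clinical
        y0 = state.as_array(clinical)
        _, samples = _integrate_cycle(
            y0, config, clinical, 0.0, SolverSettings(), None
        )

        from evlpsim.gas_exchange import breath_mixed_fractions

        wf = VentilatorWaveform.from_clinical(clinical)
        fd = breath_mixed_fractions(
            clinical.vt, config.intrinsic.v_d, clinical.fio2,
            config.constants.fico2, float(y0[1]), float(y0[2]),
        )
        dt = 1e-4

        def rk4(f, y, t0, t1):
            n = int(round((t1 - t0) / dt))
            t = t0
            integral = np.zeros(2)
            for _ in range(n):
                k1 = np.asarray(f(t, y))
                k2 = np.asarray(f(t + dt / 2, y + dt / 2 * k1))
                k3 = np.asarray(f(t + dt / 2, y + dt / 2 * k2))
                k4 = np.asarray(f(t + dt, y + dt * k3))
                integral += dt / 2 * np.array([y[3], y[4]])
                y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                integral += dt / 2 * np.array([y[3], y[4]])
                t += dt
            return y, integral

        y = y0.copy()
        y[7] = 0.0
        f_insp = _segment_rhs(config, clinical, wf, True, *fd)
        f_exp = _segment_rhs(config, clinical, wf, False, *fd)
        y, int1 = rk4(f_insp, y, 0.0, wf.t_insp)
        y, int2 = rk4(f_exp, y, wf.t_insp, wf.t_cyc)
        ref_mean_o2 = (int1[0] + int2[0]) / wf.t_cyc
        ref_mean_co2 = (int1[1] + int2[1]) / wf.t_cyc
        assert samples.mean_p_c_o2 == pytest.approx(ref_mean_o2, abs=0.1)
        assert samples.mean_p_c_co2 == pytest.approx(ref_mean_co2, abs=0.1)


class TestResampleNearest:
    def _result(self, config, default_steady, duration=5.0):
        state, _ = default_steady
        return simulate(config, duration, initial=state)

    def test_exact_grid_time(self, config, default_steady):
        result = self._result(config, default_steady)
        out = resample_nearest(result, [1.0])
        assert out["time_s"][0] == pytest.approx(1.0)
        i = int(round(1.0 / 0.01))
        assert out["p_la_o2"][0] == result.p_la_o2[i]

    def test_tie_goes_to_earlier_index(self, config, default_steady):
        result = self._result(config, default_steady)
        out = resample_nearest(result, [0.005])  # midway between 0.00 and 0.01
        assert out["time_s"][0] == pytest.approx(0.0)

    def test_sample_count_for_3s_grid(self, config, default_steady):
        result = self._result(config, default_steady, duration=18.0)
        targets = np.arange(0.0, 18.0 + 1e-9, 3.0)
        out = resample_nearest(result, targets)
        assert out["p_la_o2"].size == 7

    def test_out_of_span_error(self, config, default_steady):
        result = self._result(config, default_steady)
        with pytest.raises(ValueError, match="outside"):
            resample_nearest(result, [9999.0])


@pytest.fixture(scope="module")
def table(fast_settings):
    return run_static_scenarios(settings=fast_settings)


class TestStaticScenarios:
    def test_four_scenarios(self, table):
        assert list(table["scenario"]) == [
            "baseline", "high_dead_space", "high_shunt", "double_flow",
        ]

    def test_shunt_depresses_o2_more_than_dead_space(self, table):
        t = table.set_index("scenario")
        assert (
            t.loc["high_shunt", "p_la_o2_mean"]
            < t.loc["high_dead_space", "p_la_o2_mean"]
        )

    def test_dead_space_raises_co2_more_than_shunt(self, table):
        t = table.set_index("scenario")
        assert (
            t.loc["high_dead_space", "p_la_co2_mean"]
            > t.loc["high_shunt", "p_la_co2_mean"]
        )

    def test_double_flow_lowers_o2_raises_co2(self, table):
        t = table.set_index("scenario")
        assert t.loc["double_flow", "p_la_o2_mean"] < t.loc["baseline", "p_la_o2_mean"]
        assert t.loc["double_flow", "p_la_co2_mean"] > t.loc["baseline", "p_la_co2_mean"]


def test_result_dataframe(config, default_steady):
    state, _ = default_steady
    result = simulate(config, 1.0, initial=state)
    df = result.to_dataframe()
    assert "time_s" in df.columns
    assert "p_la_o2" in df.columns
    assert len(df) == result.time.size
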