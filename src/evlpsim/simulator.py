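"""Full six-state ODE system: assembly, integration, steady state, scenarios.

The ODE states are alveolar pressure, alveolar O2/CO2 fractions, capillary
PO2/PCO2 and bicarbonate; two auxiliary states (tidal alveolar volume and
cumulative inspired volume) are needed to evaluate the volume balance and
dead-space bookkeeping, and two quadrature states accumulate the
capillary-pressure integrals used for exact cycle means.

Integration is segment-wise: each ventilator cycle is split at the
inspiratory/expiratory discontinuity so the right-hand side is smooth on
every segment.  The mixed inspired gas fraction is held constant over each
breath (volume-weighted anatomical-dead-space rebreathing, frozen at the
end-expiratory alveolar composition of the previous breath).  Ventilator
settings taken from an input schedule are applied at cycle boundaries (a
setting change takes effect on the next breath).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import gas_exchange, lung_mechanics
from .parameters import (
    CMH2O_PER_MMHG,
    ClinicalInputs,
    ModelConfig,
    require_valid,
)
from .ventilator import VentilatorWaveform

__all__ = [
    "StateVector",
    "InputSchedule",
    "SimulationResult",
    "SolverSettings",
    "SimulationError",
    "ConvergenceError",
    "rhs",
    "simulate",
    "run_to_steady_state",
    "run_cycle_means",
    "run_static_scenarios",
    "resample_nearest",
    "cycle_stats",
]

#: Default output sampling rate [Hz].
OUTPUT_HZ = 100.0

#: Steady-state criterion: max drift of successive cycle-mean outputs [mmHg].
STEADY_TOL_MMHG = 0.05

#: Steady-state search cap [s].
STEADY_CAP_S = 600.0


class SimulationError(RuntimeError):
    """Integration failed; the message names the time and state."""


class ConvergenceError(SimulationError):
    """Steady state was not reached within the time cap."""


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive-solver settings: LSODA stiff/nonstiff switching, tight tolerance."""

    rtol: float = 1e-9
    atol: float = 1e-9
    max_step: float = 0.1
    method: str = "LSODA"


@dataclass
class StateVector:
    """Model state; defaults are the standard initial values for simulations."""

    p_a: float = 7.0          # alveolar pressure [cmH2O]
    f_a_o2: float = 0.18      # alveolar O2 fraction [-]
    f_a_co2: float = 0.030    # alveolar CO2 fraction [-]
    p_c_o2: float = 125.0     # capillary PO2 [mmHg]
    p_c_co2: float = 25.0     # capillary PCO2 [mmHg]
    z: float = 1.7e-2         # bicarbonate [mol L^-1]
    v_a: float | None = None  # elastic alveolar volume above V_A0 [L]; None -> C_stat * P_A
    v_cum: float = 0.0        # cumulative inspired volume this breath [L]

    def as_array(self, clinical: ClinicalInputs) -> np.ndarray:
        v_a = self.v_a
        if v_a is None:
            # volume-pressure closure: the elastic volume above the unstressed
            # volume is C_stat * P_A (an invariant of the mechanics pair, fixed
            # here by anchoring V_A = 0 at zero alveolar pressure)
            v_a = clinical.c_stat * self.p_a
        return np.array(
            [self.p_a, self.f_a_o2, self.f_a_co2, self.p_c_o2, self.p_c_co2,
             self.z, v_a, self.v_cum, 0.0, 0.0]
        )

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "StateVector":
        # v_a is deliberately dropped: it is re-derived from P_A via the
        # volume-pressure closure, which keeps warm starts consistent when
        # the compliance changes between runs
        return cls(
            p_a=float(y[0]), f_a_o2=float(y[1]), f_a_co2=float(y[2]),
            p_c_o2=float(y[3]), p_c_co2=float(y[4]), z=float(y[5]),
            v_a=None, v_cum=float(y[7]),
        )


class InputSchedule:
    """Piecewise-constant time courses for clinical-input fields.

    ``changes`` maps a field name (e.g. ``"fio2"``) to a sequence of
    ``(time_s, value)`` pairs with non-decreasing times.  Values before the
    first change time are taken from the base configuration.
    """

    def __init__(self, changes: Mapping[str, Sequence[tuple[float, float]]] | None = None):
        self.changes: dict[str, list[tuple[float, float]]] = {}
        for name, pairs in (changes or {}).items():
            pairs = [(float(t), float(v)) for t, v in pairs]
            times = [t for t, _ in pairs]
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValueError(f"schedule times for {name} must be non-decreasing")
            self.changes[name] = pairs

    @classmethod
    def step(cls, name: str, at: float, value: float) -> "InputSchedule":
        """Single step of one field at time ``at``."""
        return cls({name: [(at, value)]})

    def clinical_at(self, t: float, base: ClinicalInputs) -> ClinicalInputs:
        """Clinical inputs in force at time ``t``."""
        updates: dict[str, float] = {}
        for name, pairs in self.changes.items():
            i = bisect.bisect_right([p[0] for p in pairs], t) - 1
            if i >= 0:
                updates[name] = pairs[i][1]
        if not updates:
            return base
        return dc_replace(base, **updates)


@dataclass
class SimulationResult:
    """Dense (uniform-grid) time series of states and derived outputs."""

    time: np.ndarray                    # [s]
    states: dict[str, np.ndarray]       # per-state series
    p_la_o2: np.ndarray                 # [mmHg]
    p_la_co2: np.ndarray                # [mmHg]
    config: ModelConfig

    def to_dataframe(self):
        import pandas as pd

        data = {"time_s": self.time}
        data.update(self.states)
        data["p_la_o2"] = self.p_la_o2
        data["p_la_co2"] = self.p_la_co2
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------


def _segment_rhs(config: ModelConfig, clinical: ClinicalInputs, wf: VentilatorWaveform,
                 inspiring: bool, fd_o2: float, fd_co2: float):
    """Closure evaluating the smooth RHS on one segment (scalar math, hot path).

    ``t`` is cycle-relative.  Algebraic identity with the compositional
    :func:`rhs` is asserted in the test suite.
    """
    c = config.constants
    intr = config.intrinsic
    peep, t_insp = wf.peep, wf.t_insp
    slope = (wf.p_plat - peep) / t_insp
    r_aw, c_stat = intr.r_aw, clinical.c_stat
    v_a0, f_ds, f_sh = intr.v_a0, intr.f_ds, intr.f_sh
    f_ge = 1.0 - f_ds - f_sh
    split = f_ge / (f_ge + f_ds)
    p_dry0 = c.p_atm - c.p_w
    d_o2, d_co2 = c.d_o2, c.d_co2
    vdot_o2, vdot_co2 = c.vdot_o2, c.vdot_co2
    k_diff_o2 = c.d_o2_p / (c.sigma_o2 * (1.0 - f_sh) * c.v_c_tot)
    k_diff_co2 = c.d_co2_p / (c.sigma_co2 * (1.0 - f_sh) * c.v_c_tot)
    k_q = clinical.q / c.v_c_tot
    p_pa_o2, p_pa_co2 = clinical.p_pa_o2, clinical.p_pa_co2
    k_hyd = c.delta * c.l2 * clinical.h
    k_dehyd = c.delta * c.r2
    sigma_co2 = c.sigma_co2

    def f(t: float, y: np.ndarray) -> list[float]:
        p_a = y[0]
        f_o2 = y[1]
        f_co2 = y[2]
        p_c_o2 = y[3]
        p_c_co2 = y[4]
        z = y[5]
        v_a = y[6]

        p_vent = peep + slope * t if inspiring else peep
        flow = (p_vent - p_a) / r_aw
        dp_a = flow / c_stat

        v_ge = f_ge * (v_a0 + v_a)
        dry = p_dry0 + p_a * CMH2O_PER_MMHG
        p_a_o2 = f_o2 * dry
        p_a_co2 = f_co2 * dry

        if inspiring and flow > 0.0:
            v_ge_i = flow * split
            dv_cum = flow
        else:
            v_ge_i = 0.0
            dv_cum = 0.0

        diff_o2 = d_o2 * (p_c_o2 - p_a_o2)
        diff_co2 = d_co2 * (p_c_co2 - p_a_co2)
        net = diff_o2 + diff_co2
        df_o2 = (
            diff_o2 + (fd_o2 - f_o2) * v_ge_i - f_o2 * net
            + (f_o2 - 1.0) * vdot_o2 - f_o2 * vdot_co2
        ) / v_ge
        df_co2 = (
            diff_co2 + (fd_co2 - f_co2) * v_ge_i - f_co2 * net
            + (1.0 - f_co2) * vdot_co2 + f_co2 * vdot_o2
        ) / v_ge

        dp_c_o2 = k_diff_o2 * (p_a_o2 - p_c_o2) + k_q * (p_pa_o2 - p_c_o2)
        dp_c_co2 = (
            k_diff_co2 * (p_a_co2 - p_c_co2)
            + k_q * (p_pa_co2 - p_c_co2)
            + k_hyd * z / sigma_co2
            - k_dehyd * p_c_co2
        )
        dz = k_dehyd * sigma_co2 * p_c_co2 - k_hyd * z

        return [dp_a, df_o2, df_co2, dp_c_o2, dp_c_co2, dz, flow, dv_cum,
                p_c_o2, p_c_co2]

    return f


def rhs(
    t: float,
    state: Sequence[float],
    config: ModelConfig,
    schedule: InputSchedule | None = None,
    end_exp_fractions: tuple[float, float] | None = None,
) -> np.ndarray:
    """Reference RHS composed from the module-level operations.

    Pure function of ``(t, state)``: the ventilator phase follows from
    ``t mod T_cyc``.  ``end_exp_fractions`` is the frozen end-expiratory
    alveolar composition defining the breath's mixed inspired fraction
    (defaults to the current alveolar fractions).  This is the readable,
    compositional route; the integrator uses an algebraically identical
    scalar closure.
    """
    clinical = config.clinical
    if schedule is not None:
        clinical = schedule.clinical_at(t, clinical)
    wf = VentilatorWaveform.from_clinical(clinical)
    intr = config.intrinsic
    c = config.constants

    p_a, f_o2, f_co2, p_c_o2, p_c_co2, z, v_a, v_cum = (float(x) for x in state[:8])
    u = t % wf.t_cyc
    inspiring = u <= wf.t_insp
    p_vent = wf.pressure_at(t)

    flow = lung_mechanics.airflow(p_vent, p_a, intr.r_aw)
    dp_a = lung_mechanics.dPA_dt(p_vent, p_a, intr.r_aw, clinical.c_stat)
    v_a_ge, v_a_ds = lung_mechanics.partition_volumes(v_a, intr)

    gs = gas_exchange.GasState(f_o2, f_co2, p_c_o2, p_c_co2, z)
    p_a_o2, p_a_co2 = gas_exchange.alveolar_partial_pressures(f_o2, f_co2, p_a, c)
    if end_exp_fractions is None:
        end_exp_fractions = (f_o2, f_co2)
    fd_o2, fd_co2 = gas_exchange.breath_mixed_fractions(
        clinical.vt, intr.v_d, clinical.fio2, c.fico2, *end_exp_fractions
    )
    if inspiring and flow > 0.0:
        v_ge_i = flow * v_a_ge / (v_a_ge + v_a_ds)
        dv_cum = flow
    else:
        v_ge_i = 0.0
        dv_cum = 0.0
    df_o2, df_co2 = gas_exchange.alveolar_fraction_derivs(
        gs, p_a_o2, p_a_co2, fd_o2, fd_co2, v_ge_i, v_a_ge, c
    )
    v_c_ge = gas_exchange.capillary_exchange_volume(intr.f_sh, c)
    dp_c_o2, dp_c_co2 = gas_exchange.capillary_pressure_derivs(
        gs, p_a_o2, p_a_co2, v_c_ge, clinical, c
    )
    dz = gas_exchange.bicarbonate_deriv(p_c_co2, clinical.h, z, c)

    deriv = np.array([dp_a, df_o2, df_co2, dp_c_o2, dp_c_co2, dz, flow, dv_cum])
    if not np.all(np.isfinite(deriv)):
        raise SimulationError(f"non-finite derivative at t={t}: state={list(state)}")
    return deriv


# ---------------------------------------------------------------------------
# Segment-wise integration
# ---------------------------------------------------------------------------


@dataclass
class _CycleSamples:
    t: np.ndarray          # absolute time [s]
    y: np.ndarray          # state samples, shape (10, n)
    mean_p_c_o2: float     # cycle-mean capillary PO2 [mmHg]
    mean_p_c_co2: float
    clinical: ClinicalInputs


def _integrate_cycle(
    y: np.ndarray,
    config: ModelConfig,
    clinical: ClinicalInputs,
    t_start: float,
    settings: SolverSettings,
    t_eval_abs: np.ndarray | None,
) -> tuple[np.ndarray, _CycleSamples]:
    """Integrate one full ventilator cycle from a cycle start (inspiration onset)."""
    wf = VentilatorWaveform.from_clinical(clinical)
    fd_o2, fd_co2 = gas_exchange.breath_mixed_fractions(
        clinical.vt, config.intrinsic.v_d, clinical.fio2, config.constants.fico2,
        float(y[1]), float(y[2]),
    )

    y = y.copy()
    y[7] = 0.0          # new breath: reset cumulative inspired volume
    i0_o2, i0_co2 = float(y[8]), float(y[9])

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for inspiring, lo, hi in ((True, 0.0, wf.t_insp), (False, wf.t_insp, wf.t_cyc)):
        f = _segment_rhs(config, clinical, wf, inspiring, fd_o2, fd_co2)
        if t_eval_abs is None:
            t_eval = None
            n_keep = 0
        else:
            rel = t_eval_abs - t_start
            sel = rel[(rel >= lo - 1e-9) & (rel <= hi + 1e-9)]
            sel = np.clip(sel, lo, hi)
            n_keep = sel.size
            # always integrate through an evaluation at the segment end so the
            # endpoint state can be read off the last column
            if n_keep == 0 or sel[-1] < hi - 1e-12:
                t_eval = np.append(sel, hi)
            else:
                t_eval = sel
        sol = solve_ivp(
            f, (lo, hi), y,
            method=settings.method, rtol=settings.rtol, atol=settings.atol,
            max_step=settings.max_step, t_eval=t_eval,
        )
        if not sol.success:
            raise SimulationError(
                f"solver failed on segment [{t_start + lo:g}, {t_start + hi:g}]: "
                f"{sol.message}; state={y.tolist()}"
            )
        y = sol.y[:, -1].copy() if sol.y.size else y
        if n_keep:
            ts.append(sol.t[:n_keep])
            ys.append(sol.y[:, :n_keep])

    if ts:
        t_all = np.concatenate(ts) + t_start
        y_all = np.concatenate(ys, axis=1)
        keep = np.concatenate(([True], np.diff(t_all) > 1e-12))
        t_all, y_all = t_all[keep], y_all[:, keep]
    else:
        t_all = np.empty((0,))
        y_all = np.empty((10, 0))

    if not np.all(np.isfinite(y[:8])):
        raise SimulationError(f"non-finite state at t={t_start + wf.t_cyc}: {y.tolist()}")
    samples = _CycleSamples(
        t=t_all,
        y=y_all,
        mean_p_c_o2=(float(y[8]) - i0_o2) / wf.t_cyc,
        mean_p_c_co2=(float(y[9]) - i0_co2) / wf.t_cyc,
        clinical=clinical,
    )
    return y, samples


def _la_outputs(y_states: np.ndarray, clinical: ClinicalInputs, f_sh: float):
    p_la_o2 = gas_exchange.left_atrial_mixing(clinical.p_pa_o2, y_states[3], f_sh)
    p_la_co2 = gas_exchange.left_atrial_mixing(clinical.p_pa_co2, y_states[4], f_sh)
    return p_la_o2, p_la_co2


# ---------------------------------------------------------------------------
# Public drivers
# ---------------------------------------------------------------------------


def simulate(
    config: ModelConfig,
    duration: float,
    schedule: InputSchedule | None = None,
    initial: StateVector | None = None,
    settings: SolverSettings | None = None,
    sample_hz: float = OUTPUT_HZ,
    check: bool = True,
) -> SimulationResult:
    """Integrate for ``duration`` seconds and resample to a uniform output grid.

    Schedule changes take effect at the first cycle boundary at or after
    their scheduled time (a ventilator setting changes on the next breath).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if check:
        require_valid(config)
    settings = settings or SolverSettings()
    initial = initial or StateVector()

    dt = 1.0 / sample_hz
    grid = np.round(np.arange(0.0, duration + 0.5 * dt, dt), 9)
    grid = grid[grid <= duration + 1e-9]

    clinical = (schedule.clinical_at(0.0, config.clinical) if schedule
                else config.clinical)
    y = initial.as_array(clinical)

    t = 0.0
    t_chunks: list[np.ndarray] = []
    o2_chunks: list[np.ndarray] = []
    co2_chunks: list[np.ndarray] = []
    state_chunks: list[np.ndarray] = []
    f_sh = config.intrinsic.f_sh
    while t < duration - 1e-9:
        if schedule is not None:
            clinical = schedule.clinical_at(t, config.clinical)
        wf = VentilatorWaveform.from_clinical(clinical)
        y, samples = _integrate_cycle(y, config, clinical, t, settings, grid)
        if samples.t.size:
            p_la_o2, p_la_co2 = _la_outputs(samples.y, clinical, f_sh)
            t_chunks.append(samples.t)
            o2_chunks.append(p_la_o2)
            co2_chunks.append(p_la_co2)
            state_chunks.append(samples.y)
        t += wf.t_cyc

    t_all = np.concatenate(t_chunks)
    y_all = np.concatenate(state_chunks, axis=1)
    o2_all = np.concatenate(o2_chunks)
    co2_all = np.concatenate(co2_chunks)
    grid = grid[grid <= t_all[-1] + 1e-9]
    idx = np.clip(np.searchsorted(t_all, grid - 1e-9, side="left"), 0, t_all.size - 1)
    names = ["p_a", "f_a_o2", "f_a_co2", "p_c_o2", "p_c_co2", "z", "v_a"]
    states = {name: y_all[i, idx] for i, name in enumerate(names)}
    return SimulationResult(
        time=grid,
        states=states,
        p_la_o2=o2_all[idx],
        p_la_co2=co2_all[idx],
        config=config,
    )


def run_to_steady_state(
    config: ModelConfig,
    schedule: InputSchedule | None = None,
    initial: StateVector | None = None,
    settings: SolverSettings | None = None,
    steady_tol: float = STEADY_TOL_MMHG,
    cap: float = STEADY_CAP_S,
    check: bool = True,
) -> tuple[StateVector, dict[str, float]]:
    """Integrate whole cycles until the cycle-mean outputs stop drifting.

    Returns the end-cycle state and a summary with converged cycle-mean
    ``p_la_o2`` / ``p_la_co2`` [mmHg], the number of cycles, and elapsed
    simulated time.  Raises :class:`ConvergenceError` if the drift has not
    fallen below ``steady_tol`` within ``cap`` seconds.  ``check=False``
    skips normal-range validation (used for Monte-Carlo draws that follow
    sensor distributions rather than the normal ranges).
    """
    if check:
        require_valid(config)
    settings = settings or SolverSettings()
    initial = initial or StateVector()
    clinical = (schedule.clinical_at(0.0, config.clinical) if schedule
                else config.clinical)
    y = initial.as_array(clinical)
    f_sh = config.intrinsic.f_sh

    t = 0.0
    prev: tuple[float, float] | None = None
    n_cycles = 0
    while t < cap:
        if schedule is not None:
            clinical = schedule.clinical_at(t, config.clinical)
        wf = VentilatorWaveform.from_clinical(clinical)
        y, samples = _integrate_cycle(y, config, clinical, t, settings, None)
        t += wf.t_cyc
        n_cycles += 1
        mean_o2 = gas_exchange.left_atrial_mixing(clinical.p_pa_o2, samples.mean_p_c_o2, f_sh)
        mean_co2 = gas_exchange.left_atrial_mixing(clinical.p_pa_co2, samples.mean_p_c_co2, f_sh)
        if prev is not None:
            if abs(mean_o2 - prev[0]) < steady_tol and abs(mean_co2 - prev[1]) < steady_tol:
                return StateVector.from_array(y), {
                    "p_la_o2": mean_o2,
                    "p_la_co2": mean_co2,
                    "n_cycles": float(n_cycles),
                    "elapsed_s": t,
                }
        prev = (mean_o2, mean_co2)
    raise ConvergenceError(
        f"no steady state within {cap:g} s (last cycle means: "
        f"P_LA_O2={prev[0]:.3f}, P_LA_CO2={prev[1]:.3f} mmHg)"
    )


def run_cycle_means(
    config: ModelConfig,
    duration: float,
    schedule: InputSchedule | None = None,
    initial: StateVector | None = None,
    settings: SolverSettings | None = None,
) -> tuple[StateVector, np.ndarray, np.ndarray, np.ndarray]:
    """Integrate whole cycles and return per-cycle mean outputs.

    Returns ``(end_state, t_mid, p_la_o2_means, p_la_co2_means)`` where
    ``t_mid`` holds cycle midpoint times.  Cycle means come from quadrature
    states, so no dense sampling is needed (cheap; used by the study drivers).
    """
    require_valid(config)
    settings = settings or SolverSettings()
    initial = initial or StateVector()
    clinical = (schedule.clinical_at(0.0, config.clinical) if schedule
                else config.clinical)
    y = initial.as_array(clinical)
    f_sh = config.intrinsic.f_sh

    t = 0.0
    t_mid: list[float] = []
    o2: list[float] = []
    co2: list[float] = []
    while t < duration - 1e-9:
        if schedule is not None:
            clinical = schedule.clinical_at(t, config.clinical)
        wf = VentilatorWaveform.from_clinical(clinical)
        y, samples = _integrate_cycle(y, config, clinical, t, settings, None)
        t_mid.append(t + 0.5 * wf.t_cyc)
        o2.append(gas_exchange.left_atrial_mixing(clinical.p_pa_o2, samples.mean_p_c_o2, f_sh))
        co2.append(gas_exchange.left_atrial_mixing(clinical.p_pa_co2, samples.mean_p_c_co2, f_sh))
        t += wf.t_cyc
    return StateVector.from_array(y), np.array(t_mid), np.array(o2), np.array(co2)


def cycle_stats(result: SimulationResult) -> dict[str, float]:
    """Mean / min / max of the left-atrial outputs over a result window."""
    return {
        "p_la_o2_mean": float(np.mean(result.p_la_o2)),
        "p_la_o2_min": float(np.min(result.p_la_o2)),
        "p_la_o2_max": float(np.max(result.p_la_o2)),
        "p_la_co2_mean": float(np.mean(result.p_la_co2)),
        "p_la_co2_min": float(np.min(result.p_la_co2)),
        "p_la_co2_max": float(np.max(result.p_la_co2)),
    }


STATIC_SCENARIOS: tuple[dict, ...] = (
    {"name": "baseline", "f_ds": 0.25, "f_sh": 0.25, "q_l_min": 1.5},
    {"name": "high_dead_space", "f_ds": 0.50, "f_sh": 0.25, "q_l_min": 1.5},
    {"name": "high_shunt", "f_ds": 0.25, "f_sh": 0.50, "q_l_min": 1.5},
    {"name": "double_flow", "f_ds": 0.25, "f_sh": 0.25, "q_l_min": 3.0},
)


def run_static_scenarios(
    config: ModelConfig | None = None,
    window: float = 30.0,
    settings: SolverSettings | None = None,
):
    """Cycle-resolved outputs for the four standard static scenarios.

    Each scenario is run to steady state, then a ``window``-second simulation
    is summarised (mean/min/max of both outputs).  Returns a pandas DataFrame.
    """
    import pandas as pd

    from .parameters import default_config

    config = config or default_config()
    rows = []
    for sc in STATIC_SCENARIOS:
        cfg = config.with_intrinsic(f_ds=sc["f_ds"], f_sh=sc["f_sh"]).with_clinical(
            q=sc["q_l_min"] / 60.0
        )
        state, _ = run_to_steady_state(cfg, settings=settings)
        result = simulate(cfg, window, initial=state, settings=settings)
        rows.append({"scenario": sc["name"], **{k: sc[k] for k in ("f_ds", "f_sh", "q_l_min")},
                     **cycle_stats(result)})
    return pd.DataFrame(rows)


def resample_nearest(
    result: SimulationResult, target_times: Iterable[float]
) -> dict[str, np.ndarray]:
    """Nearest-neighbour resampling of the outputs onto ``target_times``.

    Ties (a target exactly midway between grid points) resolve to the earlier
    index.  Targets outside the simulated span raise ``ValueError``.
    """
    targets = np.asarray(list(target_times), dtype=float)
    t = result.time
    if targets.size and (targets.min() < t[0] - 1e-9 or targets.max() > t[-1] + 1e-9):
        raise ValueError(
            f"target times [{targets.min():g}, {targets.max():g}] outside simulated "
            f"span [{t[0]:g}, {t[-1]:g}]"
        )
    idx = np.searchsorted(t, targets, side="left")
    idx = np.clip(idx, 0, t.size - 1)
    lower = np.clip(idx - 1, 0, t.size - 1)
    choose_lower = (targets - t[lower]) <= (t[idx] - targets)
    idx = np.where(choose_lower & (idx > 0), lower, idx)
    return {
        "time_s": t[idx],
        "p_la_o2": result.p_la_o2[idx],
        "p_la_co2": result.p_la_co2[idx],
    }
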