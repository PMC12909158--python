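"""Morris elementary-effects global sensitivity analysis.

One-at-a-time randomized trajectories on a p-level grid give, per parameter
and model output, an importance score (mu*, the mean absolute elementary
effect) and an interaction/nonlinearity score (sigma, the standard deviation
of the signed elementary effects).  The three screened outputs are the
steady-state left-atrial PO2 and PCO2 and the time constant of the
left-atrial PO2 response to an inspired-O2 step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields as dc_fields, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .calibration import DegenerateFitError, fit_mono_exponential
from .parameters import (
    CLINICAL_RANGES,
    INTRINSIC_RANGES,
    ModelConfig,
    PhysicalConstants,
    default_config,
)
from .simulator import (
    SolverSettings,
    StateVector,
    run_cycle_means,
    run_to_steady_state,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MorrisDesign",
    "build_design",
    "elementary_effects",
    "scale_scores",
    "parameter_space",
    "run_sensitivity_study",
]

#: Clinical-input fields varied over their normal ranges.
CLINICAL_PARAMS = tuple(CLINICAL_RANGES)

#: Intrinsic parameters varied over their normal ranges.
INTRINSIC_PARAMS = tuple(INTRINSIC_RANGES)

#: Constants varied +/- 50% around defaults.
CONSTANT_PARAMS = tuple(f.name for f in dc_fields(PhysicalConstants))


@dataclass
class MorrisDesign:
    """Randomized one-at-a-time screening design.

    ``unit_design`` has shape ``(trajectories * (k + 1), k)`` with every
    point on the p-level grid in [0, 1]; consecutive rows within a
    trajectory differ in exactly one coordinate by +/- delta.
    """

    names: list[str]
    lows: np.ndarray
    highs: np.ndarray
    trajectories: int
    levels: int
    unit_design: np.ndarray

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def delta(self) -> float:
        return self.levels / (2.0 * (self.levels - 1))

    @property
    def physical_design(self) -> np.ndarray:
        return self.lows + self.unit_design * (self.highs - self.lows)

    def rows(self) -> list[dict[str, float]]:
        phys = self.physical_design
        return [dict(zip(self.names, row)) for row in phys]


def _one_trajectory(k: int, levels: int, rng: np.random.Generator) -> np.ndarray:
    """One Morris trajectory: (k+1, k) unit-scaled points on the level grid."""
    p = levels
    delta = p / (2.0 * (p - 1))
    n_base = p // 2  # grid values from which base +/- delta stays in [0, 1]
    directions = rng.integers(0, 2, size=k) * 2 - 1
    base_levels = rng.integers(0, n_base, size=k)
    base = base_levels / (p - 1.0)
    # decreasing moves start from the mirrored upper grid values
    base = np.where(directions > 0, base, 1.0 - base)
    order = rng.permutation(k)
    points = np.empty((k + 1, k))
    points[0] = base
    x = base.copy()
    for step, j in enumerate(order, start=1):
        x = x.copy()
        x[j] += directions[j] * delta
        points[step] = x
    return points


def build_design(
    ranges: Mapping[str, tuple[float, float]],
    trajectories: int = 75,
    levels: int = 10,
    seed: int | None = None,
    constraint: Callable[[dict[str, float]], bool] | None = None,
    max_tries: int = 100_000,
) -> MorrisDesign:
    """Build a seeded Morris design over ``ranges``.

    ``constraint`` (on physical-space points) rejects whole trajectories:
    a trajectory is resampled until all its points are feasible.
    """
    names = list(ranges)
    lows = np.array([ranges[n][0] for n in names], dtype=float)
    highs = np.array([ranges[n][1] for n in names], dtype=float)
    if np.any(highs <= lows):
        bad = [n for n, lo, hi in zip(names, lows, highs) if hi <= lo]
        raise ValueError(f"degenerate ranges for {bad}")
    if levels < 2 or levels % 2:
        raise ValueError("levels must be an even integer >= 2")
    rng = np.random.default_rng(seed)
    k = len(names)

    blocks: list[np.ndarray] = []
    tries = 0
    while len(blocks) < trajectories:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not build {trajectories} feasible trajectories in "
                f"{max_tries} tries"
            )
        points = _one_trajectory(k, levels, rng)
        if constraint is not None:
            phys = lows + points * (highs - lows)
            if not all(constraint(dict(zip(names, row))) for row in phys):
                continue
        blocks.append(points)
    return MorrisDesign(
        names=names,
        lows=lows,
        highs=highs,
        trajectories=trajectories,
        levels=levels,
        unit_design=np.vstack(blocks),
    )


def elementary_effects(design: MorrisDesign, model_outputs) -> pd.DataFrame:
    """Per-parameter Morris scores from one output value per design row.

    Trajectories containing any non-finite output are excluded (with a
    warning); the returned frame carries the exclusion count in
    ``df.attrs["n_excluded"]``.
    """
    y = np.asarray(model_outputs, dtype=float)
    n_rows = design.trajectories * (design.k + 1)
    if y.shape != (n_rows,):
        raise ValueError(f"expected {n_rows} outputs, got {y.shape}")

    effects: dict[str, list[float]] = {name: [] for name in design.names}
    n_excluded = 0
    for tr in range(design.trajectories):
        sl = slice(tr * (design.k + 1), (tr + 1) * (design.k + 1))
        y_tr = y[sl]
        if not np.all(np.isfinite(y_tr)):
            n_excluded += 1
            continue
        u_tr = design.unit_design[sl]
        for i in range(design.k):
            du = u_tr[i + 1] - u_tr[i]
            j = int(np.argmax(np.abs(du)))
            effects[design.names[j]].append((y_tr[i + 1] - y_tr[i]) / du[j])
    if n_excluded:
        warnings.warn(
            f"{n_excluded}/{design.trajectories} trajectories excluded "
            "(non-finite outputs)",
            stacklevel=2,
        )

    records = []
    for name in design.names:
        ee = np.array(effects[name])
        if ee.size == 0:
            mu_star, sigma = np.nan, np.nan
        else:
            mu_star = float(np.mean(np.abs(ee)))
            sigma = float(np.std(ee, ddof=1)) if ee.size > 1 else 0.0
        records.append({"parameter": name, "mu_star": mu_star, "sigma": sigma})
    df = pd.DataFrame.from_records(records)
    df.attrs["n_excluded"] = n_excluded
    return scale_scores(df)


def scale_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Add min-max scaled columns in [0, 1] (max exactly 1 unless all-zero)."""
    df = df.copy()
    for col in ("mu_star", "sigma"):
        vals = df[col].to_numpy(dtype=float)
        span = np.nanmax(vals) - np.nanmin(vals)
        if not np.isfinite(span) or span <= 0:
            df[col + "_scaled"] = np.where(np.isfinite(vals), 0.0, np.nan)
        else:
            df[col + "_scaled"] = (vals - np.nanmin(vals)) / span
    return df


def parameter_space(config: ModelConfig) -> dict[str, tuple[float, float]]:
    """Screening ranges: normal ranges for parameters, +/-50% for constants."""
    space: dict[str, tuple[float, float]] = {}
    space.update(CLINICAL_RANGES)
    space.update(INTRINSIC_RANGES)
    for name in CONSTANT_PARAMS:
        v = getattr(config.constants, name)
        space[name] = (0.5 * v, 1.5 * v)
    return space


def _config_from_row(config: ModelConfig, row: Mapping[str, float]) -> ModelConfig:
    clinical = {k: v for k, v in row.items() if k in CLINICAL_RANGES}
    intrinsic = {k: v for k, v in row.items() if k in INTRINSIC_RANGES}
    constants = {k: v for k, v in row.items() if k in CONSTANT_PARAMS}
    return replace(
        config,
        clinical=replace(config.clinical, **clinical),
        intrinsic=replace(config.intrinsic, **intrinsic),
        constants=replace(config.constants, **constants),
    )


def _feasible(row: Mapping[str, float]) -> bool:
    return row.get("f_ds", 0.0) + row.get("f_sh", 0.0) < 1.0 - 1e-9


def run_sensitivity_study(
    config: ModelConfig | None = None,
    trajectories: int = 75,
    levels: int = 10,
    seed: int | None = 42,
    tau_window_s: float = 300.0,
    fio2_challenge: float = 1.0,
    settings: SolverSettings | None = None,
    steady_cap_s: float = 2400.0,
) -> dict[str, pd.DataFrame]:
    """Morris screening of steady P_LA_O2, steady P_LA_CO2 and tau(P_LA_O2).

    Every design point is run to cyclic steady state (the two static
    outputs); the dynamic output is the mono-exponential time constant of
    the left-atrial PO2 response to stepping the inspired O2 fraction to
    ``fio2_challenge`` from that steady state.  Design points whose inspired
    fraction is already at the challenge level produce no step and are
    excluded from the tau scores.
    """
    config = config or default_config()
    # looser tolerance than the reporting default: screening differences are
    # orders of magnitude above the solver-convergence error
    settings = settings or SolverSettings(rtol=1e-7, atol=1e-7)
    space = parameter_space(config)
    design = build_design(
        space, trajectories=trajectories, levels=levels, seed=seed,
        constraint=_feasible,
    )

    n = len(design.unit_design)
    steady_o2 = np.full(n, np.nan)
    steady_co2 = np.full(n, np.nan)
    tau = np.full(n, np.nan)
    tau_r2 = np.full(n, np.nan)
    warm: StateVector | None = None
    for i, row in enumerate(design.rows()):
        cfg = _config_from_row(config, row)
        try:
            state, means = run_to_steady_state(
                cfg, initial=warm, settings=settings, cap=steady_cap_s
            )
        except RuntimeError:
            warm = None
            continue
        warm = state  # next design point differs in one coordinate only
        steady_o2[i] = means["p_la_o2"]
        steady_co2[i] = means["p_la_co2"]
        try:
            cfg_step = cfg.with_clinical(fio2=fio2_challenge)
            _, t_mid, o2, _ = run_cycle_means(
                cfg_step, tau_window_s, initial=state, settings=settings
            )
            fit = fit_mono_exponential(t_mid, o2, baseline=means["p_la_o2"])
            tau[i] = fit.tau
            tau_r2[i] = fit.r_squared_raw
        except (DegenerateFitError, RuntimeError):
            pass

    scores = {
        "p_la_o2": elementary_effects(design, steady_o2),
        "p_la_co2": elementary_effects(design, steady_co2),
        "tau": elementary_effects(design, tau),
    }
    for name, df in scores.items():
        df.attrs["output"] = name
    scores["tau"].attrs["tau_values"] = tau
    scores["tau"].attrs["tau_r_squared"] = tau_r2
    logger.info(
        "sensitivity study: %d rows, excluded per output: %s",
        n, {k: v.attrs["n_excluded"] for k, v in scores.items()},
    )
    return scores
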