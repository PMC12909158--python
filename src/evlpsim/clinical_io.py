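"""Monitor-record I/O and synthetic record generation.

An EVLP monitor record is a CSV time series on a uniform 3-second grid with
the clinical input channels and the measured left-atrial PO2.  Since no
clinical dataset ships with the package, :func:`generate_record` produces a
synthetic stand-in by simulating the model at known ("true") intrinsic
parameters and adding per-channel Gaussian sensor noise.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    ClinicalInputs,
    IntrinsicParams,
    ModelConfig,
    SensorAccuracy,
    default_config,
)
from .simulator import (
    InputSchedule,
    SolverSettings,
    resample_nearest,
    run_to_steady_state,
    simulate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RECORD_GRID_S",
    "RECORD_COLUMNS",
    "ClinicalRecord",
    "ChallengeScenario",
    "generate_record",
    "read_record",
    "write_record",
    "record_to_inputs",
]

#: Monitor sampling interval [s].
RECORD_GRID_S = 3.0

#: Required CSV columns, monitor units.
RECORD_COLUMNS = [
    "time_s",
    "vt_l",
    "t_insp_s",
    "t_exp_s",
    "peep_cmh2o",
    "fio2",
    "cstat_ml_per_cmh2o",
    "q_l_per_min",
    "ph",
    "ppa_o2_mmhg",
    "ppa_co2_mmhg",
    "pla_o2_mmhg",
]

#: Optional columns.
OPTIONAL_COLUMNS = ["pla_co2_mmhg"]

#: Normal ranges per column in monitor units (input channels only).
MONITOR_RANGES: dict[str, tuple[float, float]] = {
    "vt_l": (0.2, 0.8),
    "t_insp_s": (1.0, 5.0),
    "t_exp_s": (2.0, 10.0),
    "peep_cmh2o": (5.0, 12.0),
    "fio2": (0.21, 1.0),
    "cstat_ml_per_cmh2o": (20.0, 150.0),
    "q_l_per_min": (0.5, 3.0),
    "ph": (7.0, 7.5),
    "ppa_o2_mmhg": (40.0, 100.0),
    "ppa_co2_mmhg": (20.0, 45.0),
}


class RecordSchemaError(ValueError):
    """The record violates the monitor-record schema."""


@dataclass
class ClinicalRecord:
    """Monitor record: 3-s-sampled inputs plus measured left-atrial PO2."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.frame.columns]
        if missing:
            raise RecordSchemaError(f"missing record columns: {missing}")
        unknown = [
            c for c in self.frame.columns
            if c not in RECORD_COLUMNS + OPTIONAL_COLUMNS
        ]
        if unknown:
            raise RecordSchemaError(f"unknown record columns: {unknown}")
        if len(self.frame) == 0:
            raise RecordSchemaError("record is empty")
        t = self.frame["time_s"].to_numpy(dtype=float)
        if len(t) > 1 and not np.allclose(np.diff(t), RECORD_GRID_S, atol=1e-6):
            raise RecordSchemaError(
                f"time grid is not uniform at {RECORD_GRID_S:g} s spacing"
            )
        for col, (lo, hi) in MONITOR_RANGES.items():
            vals = self.frame[col].to_numpy(dtype=float)
            bad = (vals < lo - 1e-9) | (vals > hi + 1e-9)
            if bad.any():
                i = int(np.argmax(bad))
                raise RecordSchemaError(
                    f"{col}[{i}] = {vals[i]:g} outside normal range [{lo:g}, {hi:g}]"
                )
        if not np.isfinite(self.frame[RECORD_COLUMNS].to_numpy(dtype=float)).all():
            raise RecordSchemaError("record contains non-finite values")

    @property
    def time_s(self) -> np.ndarray:
        return self.frame["time_s"].to_numpy(dtype=float)

    @property
    def p_la_o2(self) -> np.ndarray:
        return self.frame["pla_o2_mmhg"].to_numpy(dtype=float)

    @property
    def epoch_length_s(self) -> float:
        t = self.time_s
        return float(t[-1] - t[0]) + RECORD_GRID_S

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ChallengeScenario:
    """Oxygenation-challenge scenario for synthetic record generation.

    Defaults: 15-minute epoch, inspired O2 stepped from 0.21 to 1.0 at the
    3-minute mark, default intrinsic parameters, sensor noise on.
    """

    duration_s: float = 900.0
    step_time_s: float = 180.0
    fio2_pre: float = 0.21
    fio2_post: float = 1.0
    intrinsic: IntrinsicParams = field(default_factory=IntrinsicParams)
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.step_time_s < self.duration_s):
            raise ValueError("step time must lie inside the epoch")

    def schedule(self) -> InputSchedule:
        return InputSchedule(
            {"fio2": [(0.0, self.fio2_pre), (self.step_time_s, self.fio2_post)]}
        )


def _truncated_noise(rng, mean, sd, lo, hi, size):
    """Gaussian noise clipped to the channel's normal range (keeps samples valid)."""
    draws = rng.normal(mean, sd, size=size)
    return np.clip(draws, lo, hi)


def generate_record(
    scenario: ChallengeScenario,
    config: ModelConfig | None = None,
    settings: SolverSettings | None = None,
    accuracy: SensorAccuracy | None = None,
) -> tuple[ClinicalRecord, np.ndarray]:
    """Simulate the scenario and sample a synthetic monitor record.

    The model is run to steady state at the pre-step inspired O2 fraction and
    then through the challenge epoch; all channels are sampled on the 3-s
    monitor grid.  With ``scenario.noise`` on, independent Gaussian sensor
    noise (clipped to each channel's normal range for the input channels) is
    added per sample; the left-atrial PO2 sensor uses the pulmonary-artery
    gas accuracy.

    Returns the record and the noise-free left-atrial PO2 truth series.
    """
    t0 = _time.perf_counter()
    config = config or default_config()
    config = replace(config, intrinsic=scenario.intrinsic)
    config = config.with_clinical(fio2=scenario.fio2_pre)
    accuracy = accuracy or SensorAccuracy()

    state, _ = run_to_steady_state(config, settings=settings)
    result = simulate(
        config,
        scenario.duration_s,
        schedule=scenario.schedule(),
        initial=state,
        settings=settings,
    )
    grid = np.arange(0.0, scenario.duration_s + 0.5 * RECORD_GRID_S, RECORD_GRID_S)
    sampled = resample_nearest(result, grid)
    truth_o2 = sampled["p_la_o2"]
    truth_co2 = sampled["p_la_co2"]
    n = grid.size

    clin = config.clinical
    fio2_series = np.where(grid >= scenario.step_time_s, scenario.fio2_post,
                           scenario.fio2_pre)
    channels: dict[str, np.ndarray] = {
        "vt_l": np.full(n, clin.vt),
        "t_insp_s": np.full(n, clin.t_insp),
        "t_exp_s": np.full(n, clin.t_exp),
        "peep_cmh2o": np.full(n, clin.peep),
        "fio2": fio2_series,
        "cstat_ml_per_cmh2o": np.full(n, clin.c_stat_ml),
        "q_l_per_min": np.full(n, clin.q_l_min),
        "ph": np.full(n, clin.ph),
        "ppa_o2_mmhg": np.full(n, clin.p_pa_o2),
        "ppa_co2_mmhg": np.full(n, clin.p_pa_co2),
    }
    pla_o2 = truth_o2.copy()
    pla_co2 = truth_co2.copy()
    if scenario.noise:
        rng = np.random.default_rng(scenario.seed)
        sds = {
            "vt_l": accuracy.vt,
            "t_insp_s": accuracy.t_insp,
            "t_exp_s": accuracy.t_exp,
            "peep_cmh2o": accuracy.peep,
            "fio2": accuracy.fio2,
            "cstat_ml_per_cmh2o": 0.0,          # no reported accuracy
            "q_l_per_min": accuracy.q * 60.0,
            "ph": accuracy.ph,
            "ppa_o2_mmhg": accuracy.p_pa_o2,
            "ppa_co2_mmhg": accuracy.p_pa_co2,
        }
        for col, sd in sds.items():
            if sd > 0:
                lo, hi = MONITOR_RANGES[col]
                channels[col] = _truncated_noise(rng, channels[col], sd, lo, hi, n)
        pla_o2 = pla_o2 + rng.normal(0.0, accuracy.p_la_o2, size=n)
        pla_co2 = pla_co2 + rng.normal(0.0, accuracy.p_la_o2, size=n)

    frame = pd.DataFrame({"time_s": grid, **channels,
                          "pla_o2_mmhg": pla_o2, "pla_co2_mmhg": pla_co2})
    record = ClinicalRecord(frame)
    logger.info(
        "generated %d-sample record (seed=%d, noise=%s) in %.2f s",
        n, scenario.seed, scenario.noise, _time.perf_counter() - t0,
    )
    return record, truth_o2


def write_record(record: ClinicalRecord, path: str | Path) -> None:
    """Write a record CSV (full float precision, comma-separated, header row)."""
    record.frame.to_csv(path, index=False, float_format="%.10g")


def read_record(path: str | Path) -> ClinicalRecord:
    """Read and schema-validate a record CSV."""
    frame = pd.read_csv(path)
    return ClinicalRecord(frame)


def record_to_inputs(
    record: ClinicalRecord,
) -> tuple[ClinicalInputs, InputSchedule, float | None]:
    """Condense a record into constant inputs plus an inspired-O2 schedule.

    Constant channels are summarised by their median (robust to sensor
    noise).  A step in the FiO2 channel is detected as the first crossing of
    the midpoint between the pre- and post-epoch medians; if the channel is
    flat no schedule entry is produced.

    Returns ``(base_inputs, schedule, step_time_s)``.
    """
    f = record.frame
    med = lambda c: float(f[c].median())  # noqa: E731
    fio2 = f["fio2"].to_numpy(dtype=float)
    t = record.time_s

    lo, hi = float(fio2.min()), float(fio2.max())
    step_time: float | None = None
    fio2_pre = float(np.median(fio2))
    schedule = InputSchedule()
    if hi - lo > 0.1:  # well above sensor noise: treat as a step channel
        midpoint = 0.5 * (lo + hi)
        above = fio2 > midpoint
        i_step = int(np.argmax(above))
        step_time = float(t[i_step])
        fio2_pre = float(np.median(fio2[:i_step])) if i_step else lo
        fio2_post = float(np.median(fio2[i_step:]))
        fio2_pre = min(max(fio2_pre, 0.21), 1.0)
        fio2_post = min(max(fio2_post, 0.21), 1.0)
        schedule = InputSchedule(
            {"fio2": [(0.0, fio2_pre), (step_time, fio2_post)]}
        )

    base = ClinicalInputs.from_monitor(
        vt=med("vt_l"),
        t_insp=med("t_insp_s"),
        t_exp=med("t_exp_s"),
        peep=med("peep_cmh2o"),
        fio2=fio2_pre,
        c_stat_ml=med("cstat_ml_per_cmh2o"),
        q_l_min=med("q_l_per_min"),
        ph=med("ph"),
        p_pa_o2=med("ppa_o2_mmhg"),
        p_pa_co2=med("ppa_co2_mmhg"),
    )
    return base, schedule, step_time
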