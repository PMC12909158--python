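"""Monte-Carlo uncertainty quantification.

Sensor-accuracy distributions of the clinically measured inputs are
propagated through the model: normals with means at the configured values
and SDs from the sensor accuracies are sampled independently per input, and
each draw is run to cyclic steady state (static mode) or through a
challenge schedule (dynamic mode).

Draws are truncated only at wide physical bounds (positive flows and
volumes, fractions in (0, 1]), not at the normal monitoring ranges:
truncating at a range boundary on which a mean sits (the inspired O2
fraction default, 0.21) would bias that input upward by ~0.8 SD and halve
its variance, distorting the propagated output statistics.  At the sensor
SDs the physical truncation is inactive in practice, so the sampled means
match the configured means.

Only the clinically measured inputs carry sensor noise; intrinsic
parameters and constants are held fixed.  Acidity is sampled on the pH
scale and converted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .parameters import (
    ClinicalInputs,
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
    "InputDistribution",
    "EnsembleSummary",
    "sample_inputs",
    "run_monte_carlo_static",
    "run_monte_carlo_dynamic",
]

#: Sampled channels: (clinical field, sampling scale).  pH is sampled on the
#: pH scale and converted to hydrogen-ion concentration.
SAMPLED_FIELDS = (
    "vt", "t_insp", "t_exp", "peep", "fio2", "q", "ph", "p_pa_o2", "p_pa_co2",
)

#: Wide physical truncation bounds per sampled channel (sampling scale).
PHYSICAL_BOUNDS: dict[str, tuple[float, float]] = {
    "vt": (0.01, 5.0),          # L
    "t_insp": (0.1, 60.0),      # s
    "t_exp": (0.1, 60.0),       # s
    "peep": (0.0, 50.0),        # cmH2O
    "fio2": (0.01, 1.0),        # -
    "q": (1e-4, 10.0 / 60.0),   # L s^-1
    "ph": (6.0, 8.0),           # -
    "p_pa_o2": (1.0, 760.0),    # mmHg
    "p_pa_co2": (1.0, 760.0),   # mmHg
}


@dataclass(frozen=True)
class InputDistribution:
    """Independent sensor-noise normals for the clinically measured inputs."""

    means: ClinicalInputs = field(default_factory=ClinicalInputs)
    sds: SensorAccuracy = field(default_factory=SensorAccuracy)

    def channel(self, name: str) -> tuple[float, float, float, float]:
        """(mean, sd, low, high) for a sampled channel, on its sampling scale."""
        mean = self.means.ph if name == "ph" else getattr(self.means, name)
        sd = getattr(self.sds, name)
        lo, hi = PHYSICAL_BOUNDS[name]
        return mean, sd, lo, hi

    def truncated_mean(self, name: str) -> float:
        """Theoretical mean of the truncated normal for a channel."""
        mean, sd, lo, hi = self.channel(name)
        if sd == 0:
            return mean
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return float(truncnorm.mean(a, b, loc=mean, scale=sd))


def sample_inputs(
    dist: InputDistribution,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> list[ClinicalInputs]:
    """Draw ``n`` independent input vectors (seeded, truncated to ranges)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draws: dict[str, np.ndarray] = {}
    for name in SAMPLED_FIELDS:
        mean, sd, lo, hi = dist.channel(name)
        if sd == 0:
            draws[name] = np.full(n, mean)
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            draws[name] = truncnorm.rvs(
                a, b, loc=mean, scale=sd, size=n, random_state=rng
            )
    out = []
    for i in range(n):
        updates = {name: float(draws[name][i]) for name in SAMPLED_FIELDS
                   if name != "ph"}
        updates["h"] = 10.0 ** -float(draws["ph"][i])
        out.append(replace(dist.means, **updates))
    return out


@dataclass
class EnsembleSummary:
    """Monte-Carlo output statistics.

    Static mode fills the scalar fields; dynamic mode additionally provides
    time-resolved bands (mean +/- SD and 2.5/97.5 percentiles).
    """

    n: int
    n_failed: int
    p_la_o2_mean: float
    p_la_o2_sd: float
    p_la_co2_mean: float
    p_la_co2_sd: float
    samples: pd.DataFrame                       # per-draw outputs
    time_s: np.ndarray | None = None
    bands: pd.DataFrame | None = None           # time-resolved statistics


def run_monte_carlo_static(
    config: ModelConfig | None = None,
    n: int = 10_000,
    seed: int | None = 0,
    settings: SolverSettings | None = None,
    accuracy: SensorAccuracy | None = None,
) -> EnsembleSummary:
    """Propagate sensor noise through steady-state simulations.

    Each draw is run to cyclic steady state (warm-started from the nominal
    steady state for speed; the converged cycle means are start-independent)
    and the cycle-mean left-atrial pressures are recorded.  Failed draws are
    excluded and counted.
    """
    config = config or default_config()
    settings = settings or SolverSettings(rtol=1e-7, atol=1e-7)
    dist = InputDistribution(means=config.clinical, sds=accuracy or SensorAccuracy())
    draws = sample_inputs(dist, n, seed=seed)

    nominal_state, _ = run_to_steady_state(config, settings=settings)
    o2 = np.full(n, np.nan)
    co2 = np.full(n, np.nan)
    n_failed = 0
    for i, clinical in enumerate(draws):
        cfg = replace(config, clinical=clinical)
        try:
            _, means = run_to_steady_state(
                cfg, initial=nominal_state, settings=settings, check=False
            )
        except RuntimeError:
            n_failed += 1
            continue
        o2[i] = means["p_la_o2"]
        co2[i] = means["p_la_co2"]
    ok = np.isfinite(o2)
    samples = pd.DataFrame({"p_la_o2": o2, "p_la_co2": co2})
    if n_failed:
        logger.warning("static Monte Carlo: %d/%d draws failed", n_failed, n)
    return EnsembleSummary(
        n=n,
        n_failed=n_failed,
        p_la_o2_mean=float(np.mean(o2[ok])),
        p_la_o2_sd=float(np.std(o2[ok], ddof=1)) if ok.sum() > 1 else 0.0,
        p_la_co2_mean=float(np.mean(co2[ok])),
        p_la_co2_sd=float(np.std(co2[ok], ddof=1)) if ok.sum() > 1 else 0.0,
        samples=samples,
    )


def run_monte_carlo_dynamic(
    config: ModelConfig | None = None,
    schedule: InputSchedule | None = None,
    duration: float = 900.0,
    n: int = 1_000,
    seed: int | None = 0,
    grid_s: float = 3.0,
    settings: SolverSettings | None = None,
    accuracy: SensorAccuracy | None = None,
) -> EnsembleSummary:
    """Propagate sensor noise through a dynamic (challenge) simulation.

    Default scenario: inspired O2 stepped to 1.0 at t = 180 s over a
    15-minute epoch.  Per-time-point mean, SD and 2.5/97.5 percentiles of
    the left-atrial PO2 across draws form the confidence bands.
    """
    config = config or default_config()
    settings = settings or SolverSettings(rtol=1e-7, atol=1e-7)
    schedule = schedule or InputSchedule.step("fio2", 180.0, 1.0)
    dist = InputDistribution(means=config.clinical, sds=accuracy or SensorAccuracy())
    draws = sample_inputs(dist, n, seed=seed)
    grid = np.arange(0.0, duration + 0.5 * grid_s, grid_s)

    nominal_state, _ = run_to_steady_state(config, settings=settings)
    traces = np.full((n, grid.size), np.nan)
    n_failed = 0
    for i, clinical in enumerate(draws):
        cfg = replace(config, clinical=clinical)
        try:
            state, _ = run_to_steady_state(
                cfg, initial=nominal_state, settings=settings, check=False
            )
            result = simulate(
                cfg, duration, schedule=schedule, initial=state,
                settings=settings, sample_hz=10.0, check=False,
            )
        except RuntimeError:
            n_failed += 1
            continue
        traces[i] = resample_nearest(result, grid)["p_la_o2"]
    ok = np.isfinite(traces).all(axis=1)
    kept = traces[ok]
    if n_failed:
        logger.warning("dynamic Monte Carlo: %d/%d draws failed", n_failed, n)
    bands = pd.DataFrame(
        {
            "time_s": grid,
            "mean": kept.mean(axis=0),
            "sd": kept.std(axis=0, ddof=1) if kept.shape[0] > 1 else 0.0,
            "p2_5": np.percentile(kept, 2.5, axis=0),
            "p97_5": np.percentile(kept, 97.5, axis=0),
        }
    )
    final = kept[:, -1]
    samples = pd.DataFrame({"p_la_o2_final": final})
    return EnsembleSummary(
        n=n,
        n_failed=n_failed,
        p_la_o2_mean=float(final.mean()),
        p_la_o2_sd=float(final.std(ddof=1)) if final.size > 1 else 0.0,
        p_la_co2_mean=float("nan"),
        p_la_co2_sd=float("nan"),
        samples=samples,
        time_s=grid,
        bands=bands,
    )
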