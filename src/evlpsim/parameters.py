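"""Model parameters, constants, normal ranges, sensor accuracies and unit handling.

All quantities are stored internally in a single canonical unit system:

* time                  s
* volume                L
* flow                  L s^-1
* airway pressure       cmH2O
* gas partial pressure  mmHg
* concentration         mol L^-1

Monitor-facing quantities that are conventionally reported in other units
(static compliance in mL cmH2O^-1, perfusate flow in L min^-1, acidity as pH)
are converted at the configuration boundary and never inside the model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Iterator, Mapping

__all__ = [
    "CMH2O_PER_MMHG",
    "ClinicalInputs",
    "IntrinsicParams",
    "PhysicalConstants",
    "SensorAccuracy",
    "ModelConfig",
    "Violation",
    "default_config",
    "validate",
    "cmh2o_to_mmhg",
    "CLINICAL_RANGES",
    "INTRINSIC_RANGES",
]

#: 1 cmH2O expressed in mmHg.
CMH2O_PER_MMHG = 0.7356


def cmh2o_to_mmhg(p: float) -> float:
    """Convert a pressure from cmH2O to mmHg."""
    return p * CMH2O_PER_MMHG


def mmhg_to_cmh2o(p: float) -> float:
    """Convert a pressure from mmHg to cmH2O."""
    return p / CMH2O_PER_MMHG


# ---------------------------------------------------------------------------
# Normal ranges (canonical units).  Each entry: (low, high).
# ---------------------------------------------------------------------------

CLINICAL_RANGES: dict[str, tuple[float, float]] = {
    "vt": (0.2, 0.8),                   # L
    "t_insp": (1.0, 5.0),               # s
    "t_exp": (2.0, 10.0),               # s
    "peep": (5.0, 12.0),                # cmH2O
    "fio2": (0.21, 1.0),                # -
    "c_stat": (0.020, 0.150),           # L cmH2O^-1  (20-150 mL cmH2O^-1)
    "q": (0.5 / 60.0, 3.0 / 60.0),      # L s^-1      (0.5-3 L min^-1)
    "h": (10.0 ** -7.5, 10.0 ** -7.0),  # mol L^-1    (pH 7.5-7.0)
    "p_pa_o2": (40.0, 100.0),           # mmHg
    "p_pa_co2": (20.0, 45.0),           # mmHg
}

INTRINSIC_RANGES: dict[str, tuple[float, float]] = {
    "f_ds": (0.0, 0.95),
    "f_sh": (0.0, 0.95),
    "v_d": (0.15, 0.35),                # L
    "v_a0": (1.0, 2.5),                 # L
    "r_aw": (10.0, 25.0),               # cmH2O s L^-1
}


@dataclass(frozen=True)
class ClinicalInputs:
    """Ventilator and perfusion settings measured on the monitor.

    Fields are canonical-unit values; use :meth:`from_monitor` to build from
    monitor-convention units (compliance in mL cmH2O^-1, flow in L min^-1, pH).
    """

    vt: float = 0.5             # tidal volume [L]
    t_insp: float = 3.0         # inspiration duration [s]
    t_exp: float = 6.0          # expiration duration [s]
    peep: float = 6.0           # positive end-expiratory pressure [cmH2O]
    fio2: float = 0.21          # inspired O2 fraction [-]
    c_stat: float = 0.080       # static compliance [L cmH2O^-1]
    q: float = 1.5 / 60.0       # perfusate flow [L s^-1]
    h: float = 10.0 ** -7.3     # hydrogen-ion concentration [mol L^-1]
    p_pa_o2: float = 70.0       # pulmonary-artery PO2 [mmHg]
    p_pa_co2: float = 35.0      # pulmonary-artery PCO2 [mmHg]

    @property
    def ph(self) -> float:
        return -math.log10(self.h)

    @property
    def c_stat_ml(self) -> float:
        """Static compliance in monitor units [mL cmH2O^-1]."""
        return self.c_stat * 1000.0

    @property
    def q_l_min(self) -> float:
        """Perfusate flow in monitor units [L min^-1]."""
        return self.q * 60.0

    @classmethod
    def from_monitor(
        cls,
        *,
        vt: float = 0.5,
        t_insp: float = 3.0,
        t_exp: float = 6.0,
        peep: float = 6.0,
        fio2: float = 0.21,
        c_stat_ml: float = 80.0,
        q_l_min: float = 1.5,
        ph: float = 7.3,
        p_pa_o2: float = 70.0,
        p_pa_co2: float = 35.0,
    ) -> "ClinicalInputs":
        """Build from monitor-convention units, converting at the boundary."""
        return cls(
            vt=vt,
            t_insp=t_insp,
            t_exp=t_exp,
            peep=peep,
            fio2=fio2,
            c_stat=c_stat_ml / 1000.0,
            q=q_l_min / 60.0,
            h=10.0 ** -ph,
            p_pa_o2=p_pa_o2,
            p_pa_co2=p_pa_co2,
        )


@dataclass(frozen=True)
class IntrinsicParams:
    """Intrinsic (non-measurable, estimated) lung properties."""

    f_ds: float = 0.25          # alveolar dead-space fraction [-]
    f_sh: float = 0.25          # intrapulmonary shunt fraction [-]
    v_d: float = 0.25           # anatomical dead-space volume [L]
    v_a0: float = 1.5           # unstressed lung volume [L]
    r_aw: float = 15.0          # airway resistance [cmH2O s L^-1]


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical and physiological constants."""

    fico2: float = 4.0e-4       # inspired CO2 fraction [-]
    p_atm: float = 760.0        # atmospheric pressure [mmHg]
    p_w: float = 47.0           # water vapour pressure [mmHg]
    vdot_o2: float = 1.5e-4     # metabolic O2 consumption [L s^-1]
    vdot_co2: float = 1.2e-4    # metabolic CO2 production [L s^-1]
    d_o2: float = 3.5e-4        # O2 diffusion capacity [L s^-1 mmHg^-1]
    d_o2_p: float = 1.56e-5     # O2 diffusion capacity [mol s^-1 mmHg^-1]
    d_co2: float = 7.08e-4      # CO2 diffusion capacity [L s^-1 mmHg^-1]
    d_co2_p: float = 3.16e-5    # CO2 diffusion capacity [mol s^-1 mmHg^-1]
    sigma_o2: float = 1.4e-6    # O2 solubility in perfusate [mol L^-1 mmHg^-1]
    sigma_co2: float = 3.3e-5   # CO2 solubility [mol L^-1 mmHg^-1]
    v_c_tot: float = 7.1e-2     # total capillary volume [L]
    delta: float = 10.0 ** 1.9  # buffering acceleration rate [-]
    r2: float = 0.12            # dehydration reaction rate [s^-1]
    l2: float = 164.0e3         # hydration reaction rate [L mol^-1 s^-1]


@dataclass(frozen=True)
class SensorAccuracy:
    """Per-channel measurement standard deviations (sensor accuracy).

    ``ph`` is the SD on the pH scale; ``q`` is already in L s^-1.  The
    left-atrial PO2 sensor is assigned the pulmonary-artery gas accuracy.
    """

    vt: float = 2.6e-2          # L
    t_insp: float = 5.1e-2      # s
    t_exp: float = 5.1e-2       # s
    peep: float = 1.0           # cmH2O
    fio2: float = 1.3e-2        # -
    q: float = 8.5e-4           # L s^-1
    ph: float = 5.1e-2          # -
    p_pa_o2: float = 5.1        # mmHg
    p_pa_co2: float = 5.1       # mmHg

    @property
    def p_la_o2(self) -> float:
        return self.p_pa_o2

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ModelConfig:
    """Full model configuration: clinical inputs, intrinsic parameters, constants."""

    clinical: ClinicalInputs = field(default_factory=ClinicalInputs)
    intrinsic: IntrinsicParams = field(default_factory=IntrinsicParams)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def with_clinical(self, **kwargs: float) -> "ModelConfig":
        return replace(self, clinical=replace(self.clinical, **kwargs))

    def with_intrinsic(self, **kwargs: float) -> "ModelConfig":
        return replace(self, intrinsic=replace(self.intrinsic, **kwargs))

    def with_constants(self, **kwargs: float) -> "ModelConfig":
        return replace(self, constants=replace(self.constants, **kwargs))


def default_config() -> ModelConfig:
    """Configuration with every field at its default value."""
    return ModelConfig()


@dataclass(frozen=True)
class Violation:
    """A single parameter-range or composite-invariant violation."""

    field: str
    value: float
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value:g}: {self.message}"


def _check_ranges(
    obj: Any, ranges: Mapping[str, tuple[float, float]]
) -> Iterator[Violation]:
    for name, (lo, hi) in ranges.items():
        value = getattr(obj, name)
        if not math.isfinite(value):
            yield Violation(name, value, "non-finite value")
        elif not (lo <= value <= hi):
            yield Violation(name, value, f"outside normal range [{lo:g}, {hi:g}]")


def validate(config: ModelConfig) -> list[Violation]:
    """Check every parameter against its normal range and composite invariants.

    Returns an empty list iff the configuration is admissible.  Violations are
    data, not exceptions: callers decide whether to raise.
    """
    out: list[Violation] = []
    out.extend(_check_ranges(config.clinical, CLINICAL_RANGES))
    out.extend(_check_ranges(config.intrinsic, INTRINSIC_RANGES))
    intr = config.intrinsic
    if intr.f_ds + intr.f_sh >= 1.0:
        out.append(
            Violation(
                "f_ds+f_sh",
                intr.f_ds + intr.f_sh,
                "F_ds + F_sh >= 1 leaves no gas-exchange compartment",
            )
        )
    const = config.constants
    for f in fields(const):
        value = getattr(const, f.name)
        if not (math.isfinite(value) and value > 0):
            out.append(Violation(f.name, value, "constant must be positive and finite"))
    return out


def require_valid(config: ModelConfig) -> ModelConfig:
    """Raise ``ValueError`` listing all violations if the config is invalid."""
    violations = validate(config)
    if violations:
        raise ValueError(
            "invalid model configuration: " + "; ".join(str(v) for v in violations)
        )
    return config


# ---------------------------------------------------------------------------
# Config file round trip (JSON / YAML).  Files use monitor units for the
# clinical block (cstat_ml_per_cmh2o, q_l_per_min, ph), matching what an EVLP
# console displays; intrinsic parameters and constants are canonical.
# ---------------------------------------------------------------------------

_CLINICAL_FILE_KEYS = {
    "vt": "vt",
    "t_insp": "t_insp",
    "t_exp": "t_exp",
    "peep": "peep",
    "fio2": "fio2",
    "cstat_ml_per_cmh2o": "c_stat_ml",
    "q_l_per_min": "q_l_min",
    "ph": "ph",
    "p_pa_o2": "p_pa_o2",
    "p_pa_co2": "p_pa_co2",
}


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    clin = config.clinical
    clinical = {
        "vt": clin.vt,
        "t_insp": clin.t_insp,
        "t_exp": clin.t_exp,
        "peep": clin.peep,
        "fio2": clin.fio2,
        "cstat_ml_per_cmh2o": clin.c_stat_ml,
        "q_l_per_min": clin.q_l_min,
        "ph": clin.ph,
        "p_pa_o2": clin.p_pa_o2,
        "p_pa_co2": clin.p_pa_co2,
    }
    intrinsic = {f.name: getattr(config.intrinsic, f.name) for f in fields(IntrinsicParams)}
    constants = {f.name: getattr(config.constants, f.name) for f in fields(PhysicalConstants)}
    return {"clinical": clinical, "intrinsic": intrinsic, "constants": constants}


def config_from_dict(data: Mapping[str, Any]) -> ModelConfig:
    """Build a config from a parsed mapping; unknown keys are rejected."""
    unknown = set(data) - {"clinical", "intrinsic", "constants"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    clinical_data = dict(data.get("clinical", {}))
    unknown = set(clinical_data) - set(_CLINICAL_FILE_KEYS)
    if unknown:
        raise ValueError(f"unknown clinical config keys: {sorted(unknown)}")
    clinical = ClinicalInputs.from_monitor(
        **{_CLINICAL_FILE_KEYS[k]: float(v) for k, v in clinical_data.items()}
    )

    intrinsic_data = dict(data.get("intrinsic", {}))
    valid = {f.name for f in fields(IntrinsicParams)}
    unknown = set(intrinsic_data) - valid
    if unknown:
        raise ValueError(f"unknown intrinsic config keys: {sorted(unknown)}")
    intrinsic = IntrinsicParams(**{k: float(v) for k, v in intrinsic_data.items()})

    constants_data = dict(data.get("constants", {}))
    valid = {f.name for f in fields(PhysicalConstants)}
    unknown = set(constants_data) - valid
    if unknown:
        raise ValueError(f"unknown constants config keys: {sorted(unknown)}")
    constants = PhysicalConstants(**{k: float(v) for k, v in constants_data.items()})

    return ModelConfig(clinical=clinical, intrinsic=intrinsic, constants=constants)


def load_config(path: str | Path) -> ModelConfig:
    """Load a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} does not contain a mapping")
    return config_from_dict(data)


def save_config(config: ModelConfig, path: str | Path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))
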