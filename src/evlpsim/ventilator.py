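"""Pressure-controlled ventilator waveform.

The driving pressure rises linearly from PEEP to the plateau pressure over
the inspiratory time, then drops instantaneously back to PEEP for the
expiratory time.  The plateau pressure is chosen so that, through the static
compliance, the set tidal volume is delivered.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ClinicalInputs

__all__ = ["VentilatorWaveform", "plateau_pressure", "pressure_at"]


def plateau_pressure(peep: float, vt: float, c_stat: float) -> float:
    """Plateau pressure [cmH2O] needed to deliver ``vt`` at compliance ``c_stat``.

    Parameters
    ----------
    peep : baseline pressure [cmH2O]
    vt : set tidal volume [L]
    c_stat : static compliance [L cmH2O^-1]; must be positive.
    """
    if c_stat <= 0:
        raise ValueError(f"static compliance must be positive, got {c_stat!r}")
    return peep + vt / c_stat


@dataclass(frozen=True)
class VentilatorWaveform:
    """One ventilator cycle: linear ramp then constant PEEP."""

    peep: float      # [cmH2O]
    p_plat: float    # [cmH2O]
    t_insp: float    # [s]
    t_exp: float     # [s]

    def __post_init__(self) -> None:
        if self.t_insp <= 0 or self.t_exp <= 0:
            raise ValueError("inspiratory and expiratory times must be positive")
        if self.p_plat < self.peep:
            raise ValueError("plateau pressure below PEEP")

    @property
    def t_cyc(self) -> float:
        """Cycle period [s]."""
        return self.t_insp + self.t_exp

    @classmethod
    def from_clinical(cls, clinical: ClinicalInputs) -> "VentilatorWaveform":
        return cls(
            peep=clinical.peep,
            p_plat=plateau_pressure(clinical.peep, clinical.vt, clinical.c_stat),
            t_insp=clinical.t_insp,
            t_exp=clinical.t_exp,
        )

    def pressure_at(self, t: float) -> float:
        """Driving pressure [cmH2O] at time ``t`` (t = 0 starts inspiration)."""
        u = t % self.t_cyc
        if u <= self.t_insp:
            return self.peep + (self.p_plat - self.peep) * u / self.t_insp
        return self.peep


def pressure_at(t: float, wf: VentilatorWaveform) -> float:
    """Functional alias for :meth:`VentilatorWaveform.pressure_at`."""
    return wf.pressure_at(t)
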