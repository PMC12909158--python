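"""Single-compartment lung mechanics.

A resistive airway element in series with an elastic alveolar compartment:
alveolar pressure relaxes toward the driving pressure with time constant
R_aw * C_stat, and the same pressure difference across the airway resistance
sets the airflow.  The instantaneous total alveolar volume (unstressed volume
plus tidal excursion) is partitioned into gas-exchange, alveolar-dead-space
and shunt fractions.
"""

from __future__ import annotations

from .parameters import IntrinsicParams

__all__ = ["dPA_dt", "airflow", "partition_volumes"]


def dPA_dt(p_vent: float, p_a: float, r_aw: float, c_stat: float) -> float:
    """Rate of change of alveolar pressure [cmH2O s^-1]."""
    return (p_vent - p_a) / (r_aw * c_stat)


def airflow(p_vent: float, p_a: float, r_aw: float) -> float:
    """Airflow through the airways [L s^-1]; positive into the alveoli."""
    return (p_vent - p_a) / r_aw


def partition_volumes(v_a: float, intrinsic: IntrinsicParams) -> tuple[float, float]:
    """Split the total alveolar volume into gas-exchange and dead-space parts.

    ``v_a`` is the tidal volume above the unstressed volume.  The dead-space
    and shunt compartments are fixed fractions of the instantaneous total
    volume, so the gas-exchange fraction is ``1 - f_ds - f_sh``.

    Returns
    -------
    (v_a_ge, v_a_ds) : gas-exchange and alveolar-dead-space volumes [L].
    """
    v_tot = intrinsic.v_a0 + v_a
    if v_tot <= 0:
        raise ValueError(f"total alveolar volume must be positive, got {v_tot!r}")
    f_ge = 1.0 - intrinsic.f_ds - intrinsic.f_sh
    if f_ge <= 0:
        raise ValueError("F_ds + F_sh >= 1 leaves no gas-exchange compartment")
    return f_ge * v_tot, intrinsic.f_ds * v_tot
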