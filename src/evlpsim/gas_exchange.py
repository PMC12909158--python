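"""Alveolar-capillary gas exchange, bicarbonate buffering and shunt mixing.

The alveolar gas-fraction balances account for membrane diffusion,
inspiratory refreshment, the total-molar-flux normalisation and lung
metabolism.  The capillary partial-pressure balances account for membrane
diffusion and perfusate refreshment; the CO2 balance additionally exchanges
with a bicarbonate pool.  A single well-mixed capillary compartment is used,
so the end-capillary pressure is identified with the capillary state
(the only closure consistent with a zero-dimensional model).
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import CMH2O_PER_MMHG, ClinicalInputs, PhysicalConstants

__all__ = [
    "GasState",
    "alveolar_partial_pressures",
    "mixed_inspired_fractions",
    "breath_mixed_fractions",
    "alveolar_fraction_derivs",
    "capillary_pressure_derivs",
    "bicarbonate_deriv",
    "left_atrial_mixing",
    "diffusive_fluxes",
    "capillary_exchange_volume",
]


@dataclass(frozen=True)
class GasState:
    """Gas-exchange state: alveolar fractions, capillary pressures, bicarbonate."""

    f_a_o2: float    # alveolar O2 fraction [-]
    f_a_co2: float   # alveolar CO2 fraction [-]
    p_c_o2: float    # capillary PO2 [mmHg]
    p_c_co2: float   # capillary PCO2 [mmHg]
    z: float         # bicarbonate concentration [mol L^-1]


def alveolar_partial_pressures(
    f_a_o2: float,
    f_a_co2: float,
    p_a: float,
    constants: PhysicalConstants,
) -> tuple[float, float]:
    """Alveolar partial pressures [mmHg] from gas fractions.

    The absolute alveolar pressure is atmospheric plus the airway-referenced
    alveolar pressure ``p_a`` [cmH2O]; each fraction multiplies the dry-gas
    pressure (absolute minus water vapour).
    """
    dry = constants.p_atm + p_a * CMH2O_PER_MMHG - constants.p_w
    return f_a_o2 * dry, f_a_co2 * dry


def mixed_inspired_fractions(
    inspired_volume_so_far: float,
    v_d: float,
    fio2: float,
    fico2: float,
    end_exp_f_a_o2: float,
    end_exp_f_a_co2: float,
) -> tuple[float, float]:
    """Gas fractions entering the alveoli during inspiration (plug-flow rebreathing).

    The first ``v_d`` litres of each breath re-deliver the anatomical
    dead-space content, frozen at the previous end-expiratory alveolar
    fractions; beyond that the fresh set fractions arrive.

    This sharp-front variant is provided for analysis; the simulator uses the
    volume-weighted per-breath mixture :func:`breath_mixed_fractions`, which
    reproduces reported steady-state behaviour.
    """
    if inspired_volume_so_far < v_d:
        return end_exp_f_a_o2, end_exp_f_a_co2
    return fio2, fico2


def breath_mixed_fractions(
    vt: float,
    v_d: float,
    fio2: float,
    fico2: float,
    end_exp_f_a_o2: float,
    end_exp_f_a_co2: float,
) -> tuple[float, float]:
    """Mixed inspired gas fractions for one breath (volume-weighted).

    Each tidal volume re-delivers the anatomical dead-space content (at the
    previous end-expiratory alveolar composition) followed by fresh gas; the
    mixture entering the alveoli is the tidal-volume-weighted average,
    constant over the breath:

        F_D = (V_D * F_A,ee + (Vt - V_D) * Fi) / Vt
    """
    if vt <= 0:
        raise ValueError(f"tidal volume must be positive, got {vt!r}")
    w = min(max(v_d / vt, 0.0), 1.0)
    return (
        w * end_exp_f_a_o2 + (1.0 - w) * fio2,
        w * end_exp_f_a_co2 + (1.0 - w) * fico2,
    )


def diffusive_fluxes(
    p_a_o2: float,
    p_a_co2: float,
    p_c_o2: float,
    p_c_co2: float,
    constants: PhysicalConstants,
) -> tuple[float, float]:
    """Volumetric diffusive fluxes into the alveolar gas [L s^-1], per gas."""
    return (
        constants.d_o2 * (p_c_o2 - p_a_o2),
        constants.d_co2 * (p_c_co2 - p_a_co2),
    )


def alveolar_fraction_derivs(
    state: GasState,
    p_a_o2: float,
    p_a_co2: float,
    f_d_o2: float,
    f_d_co2: float,
    vdot_a_ge_i: float,
    v_a_ge: float,
    constants: PhysicalConstants,
) -> tuple[float, float]:
    """Time derivatives of the alveolar O2 and CO2 fractions [s^-1].

    Terms: membrane diffusion, inspiratory refreshment toward the mixed
    inspired fractions, normalisation by the net molar flux, and metabolic
    O2 consumption / CO2 production.
    """
    diff_o2, diff_co2 = diffusive_fluxes(
        p_a_o2, p_a_co2, state.p_c_o2, state.p_c_co2, constants
    )
    net_diffusion = diff_o2 + diff_co2
    f_o2 = state.f_a_o2
    f_co2 = state.f_a_co2
    df_o2 = (
        diff_o2
        + (f_d_o2 - f_o2) * vdot_a_ge_i
        - f_o2 * net_diffusion
        + (f_o2 - 1.0) * constants.vdot_o2
        - f_o2 * constants.vdot_co2
    ) / v_a_ge
    df_co2 = (
        diff_co2
        + (f_d_co2 - f_co2) * vdot_a_ge_i
        - f_co2 * net_diffusion
        + (1.0 - f_co2) * constants.vdot_co2
        + f_co2 * constants.vdot_o2
    ) / v_a_ge
    return df_o2, df_co2


def capillary_exchange_volume(f_sh: float, constants: PhysicalConstants) -> float:
    """Capillary volume available for exchange [L]: the non-shunted fraction."""
    return (1.0 - f_sh) * constants.v_c_tot


def capillary_pressure_derivs(
    state: GasState,
    p_a_o2: float,
    p_a_co2: float,
    v_c_ge: float,
    clinical: ClinicalInputs,
    constants: PhysicalConstants,
) -> tuple[float, float]:
    """Time derivatives of capillary PO2 and PCO2 [mmHg s^-1].

    Membrane diffusion plus perfusate refreshment toward the pulmonary-artery
    pressures; CO2 additionally exchanges with bicarbonate (the exact negative
    of the bicarbonate balance, converted to pressure units by the CO2
    solubility, so total CO2 is conserved between the two pools).
    """
    dp_o2 = (
        constants.d_o2_p / (constants.sigma_o2 * v_c_ge) * (p_a_o2 - state.p_c_o2)
        + clinical.q / constants.v_c_tot * (clinical.p_pa_o2 - state.p_c_o2)
    )
    dp_co2 = (
        constants.d_co2_p / (constants.sigma_co2 * v_c_ge) * (p_a_co2 - state.p_c_co2)
        + clinical.q / constants.v_c_tot * (clinical.p_pa_co2 - state.p_c_co2)
        + constants.delta * constants.l2 * clinical.h * state.z / constants.sigma_co2
        - constants.delta * constants.r2 * state.p_c_co2
    )
    return dp_o2, dp_co2


def bicarbonate_deriv(
    p_c_co2: float,
    h: float,
    z: float,
    constants: PhysicalConstants,
) -> float:
    """Rate of change of bicarbonate concentration [mol L^-1 s^-1]."""
    return (
        constants.delta * constants.r2 * constants.sigma_co2 * p_c_co2
        - constants.delta * constants.l2 * h * z
    )


def left_atrial_mixing(p_pa_gas: float, p_c_end_gas: float, f_sh: float) -> float:
    """Left-atrial partial pressure [mmHg]: shunt-weighted mix of PA and end-capillary."""
    return p_pa_gas * f_sh + (1.0 - f_sh) * p_c_end_gas
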