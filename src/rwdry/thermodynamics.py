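"""Transition-state thermodynamics of the drying process.

From the Arrhenius parameters (Ea, D0) the activation enthalpy, entropy and
Gibbs free energy at each drying temperature are

    dH = Ea - R T
    dS = R [ln D0 - ln(Kb/h) - ln T]
    dG = dH - T dS

with T in kelvin, Kb/h the Boltzmann/Planck ratio.  Outputs are reported in
kJ/mol and kJ/(mol K).
"""

from __future__ import annotations

import math

import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = ["enthalpy", "entropy", "gibbs", "thermo_table"]


def _kelvin(temperature_C: float) -> float:
    return temperature_C + 273.15


def enthalpy(Ea_J_per_mol: float, temperature_C: float,
             constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Activation enthalpy dH = Ea - R T, in kJ/mol."""
    if Ea_J_per_mol <= 0:
        raise ValueError("Ea must be positive")
    return (Ea_J_per_mol - constants.R_J_per_molK * _kelvin(temperature_C)) / 1000.0


def entropy(D0_m2_s: float, temperature_C: float,
            constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Activation entropy dS = R [ln D0 - ln(Kb/h) - ln T], in kJ/(mol K)."""
    if D0_m2_s <= 0:
        raise ValueError("D0 must be positive")
    kb_over_h = constants.boltzmann_J_per_K / constants.planck_J_s
    T = _kelvin(temperature_C)
    return constants.R_J_per_molK * (math.log(D0_m2_s) - math.log(kb_over_h) - math.log(T)) / 1000.0


def gibbs(dH_kJ_per_mol: float, dS_kJ_per_molK: float, temperature_C: float) -> float:
    """Gibbs free energy dG = dH - T dS, in kJ/mol (T in kelvin)."""
    return dH_kJ_per_mol - _kelvin(temperature_C) * dS_kJ_per_molK


def thermo_table(Ea_J_per_mol: float, D0_m2_s: float, temperatures_C,
                 constants: PhysicalConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Per-temperature dH/dS/dG table; dG = dH - T dS holds by construction."""
    rows = []
    for T in temperatures_C:
        dH = enthalpy(Ea_J_per_mol, T, constants)
        dS = entropy(D0_m2_s, T, constants)
        rows.append({
            "temperature_C": T,
            "dH_kJ_per_mol": dH,
            "dS_kJ_per_molK": dS,
            "dG_kJ_per_mol": gibbs(dH, dS, T),
        })
    return pd.DataFrame(rows)
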