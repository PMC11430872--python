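"""Specific energy consumption and greenhouse-gas accounting.

SEC is metered electrical energy per kg of water removed (kWh/kg).  The
"real" SEC refers consumption back to the power plant through a combined
plant/transmission efficiency (0.871 by default), and emission intensities
multiply SEC_real by a per-pollutant emission factor:

    SEC_real = SEC / eta_plant
    intensity = SEC_real * EF * (1 - ER/100)        [kg pollutant / kg water]

Default emission factors are for a fossil-fuel combined-cycle plant:
CO2 622 g/kWh, NOx 3.78 g/kWh.  ER is an optional emission-reduction
percentage (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EmissionSettings",
    "EnergyRecord",
    "water_removed",
    "specific_energy",
    "emission_intensity",
    "percent_change",
    "energy_record",
]


@dataclass(frozen=True)
class EmissionSettings:
    ef_co2_g_per_kWh: float = 622.0
    ef_nox_g_per_kWh: float = 3.78
    er_pct: float = 0.0
    plant_efficiency: float = 0.871

    def __post_init__(self) -> None:
        if self.ef_co2_g_per_kWh <= 0 or self.ef_nox_g_per_kWh <= 0:
            raise ValueError("emission factors must be positive")
        if not 0 <= self.er_pct <= 100:
            raise ValueError("er_pct must lie in [0, 100]")
        if not 0 < self.plant_efficiency <= 1:
            raise ValueError("plant_efficiency must lie in (0, 1]")

    def factor_g_per_kWh(self, pollutant: str) -> float:
        try:
            return {"co2": self.ef_co2_g_per_kWh, "nox": self.ef_nox_g_per_kWh}[pollutant.lower()]
        except KeyError:
            raise ValueError(f"unknown pollutant {pollutant!r}; expected 'co2' or 'nox'") from None


@dataclass
class EnergyRecord:
    temperature_C: float
    total_kWh: float
    water_removed_kg: float
    sec_kWh_per_kg: float
    sec_real_kWh_per_kg: float
    co2_kg_per_kg: float
    nox_kg_per_kg: float


def water_removed(initial_mass_kg: float, M0_wb_pct: float, Mf_wb_pct: float) -> float:
    """Mass of water removed in drying from M0 to Mf percent wet basis.

    Mass balance on the fixed dry matter: m_w = m0 (M0 - Mf) / (100 - Mf).
    """
    if not 0 <= Mf_wb_pct < M0_wb_pct < 100:
        raise ValueError("require 0 <= Mf < M0 < 100 (percent wet basis)")
    if initial_mass_kg <= 0:
        raise ValueError("initial mass must be positive")
    return initial_mass_kg * (M0_wb_pct - Mf_wb_pct) / (100.0 - Mf_wb_pct)


def specific_energy(total_kWh: float, water_removed_kg: float) -> float:
    """SEC in kWh per kg water removed."""
    if water_removed_kg <= 0:
        raise ValueError("water_removed_kg must be positive")
    if total_kWh < 0:
        raise ValueError("total energy cannot be negative")
    return total_kWh / water_removed_kg


def emission_intensity(sec_kWh_per_kg: float, settings: EmissionSettings,
                       pollutant: str) -> float:
    """kg of pollutant emitted per kg of water removed."""
    if sec_kWh_per_kg < 0:
        raise ValueError("SEC cannot be negative")
    sec_real = sec_kWh_per_kg / settings.plant_efficiency
    ef_kg = settings.factor_g_per_kWh(pollutant) / 1000.0
    return sec_real * ef_kg * (1.0 - settings.er_pct / 100.0)


def percent_change(reference_value: float, new_value: float) -> float:
    """Percent decrease from the reference: 100 (ref - new)/ref (positive = drop)."""
    if reference_value == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (reference_value - new_value) / reference_value


def energy_record(temperature_C: float, total_kWh: float, water_removed_kg: float,
                  settings: EmissionSettings = EmissionSettings()) -> EnergyRecord:
    """Assemble the full per-run energy/emissions record."""
    sec = specific_energy(total_kWh, water_removed_kg)
    return EnergyRecord(
        temperature_C=temperature_C,
        total_kWh=total_kWh,
        water_removed_kg=water_removed_kg,
        sec_kWh_per_kg=sec,
        sec_real_kWh_per_kg=sec / settings.plant_efficiency,
        co2_kg_per_kg=emission_intensity(sec, settings, "co2"),
        nox_kg_per_kg=emission_intensity(sec, settings, "nox"),
    )
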