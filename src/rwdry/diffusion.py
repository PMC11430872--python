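"""Effective moisture diffusivity (Fick slab, first-term solution) and its
Arrhenius temperature dependence.

For long drying times the slab solution of Fick's second law reduces to

    ln MR(t) = ln(8/pi^2) - (pi^2 Deff / (4 L^2)) t

so an OLS line of ln(MR) on t (seconds) has slope -K1 with
K1 = pi^2 Deff / (4 L^2), giving Deff = 4 L^2 K1 / pi^2.  Over temperature,
Deff = D0 exp(-Ea / (R T)) — an OLS line of ln(Deff) on 1/T yields the
activation energy Ea = -slope * R and pre-exponential D0 = exp(intercept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import R_J_PER_MOL_K
from .kinetics import MoistureSeries

__all__ = [
    "DiffusionSettings",
    "DiffusionResult",
    "ArrheniusModel",
    "ArrheniusResults",
    "deff_from_series",
    "arrhenius_fit",
]


@dataclass(frozen=True)
class DiffusionSettings:
    """Slab geometry and data-window settings for the log-MR regression.

    half_thickness_m : slab half-thickness L in metres.  Default 1.5e-4 m
        (a 0.3 mm leaf).  Absolute Deff scales with L^2; the activation
        energy is independent of L (L only shifts the Arrhenius intercept).
    mr_floor : smallest MR retained in the regression (ln amplifies noise
        near zero).
    include_t0 : keep the t = 0 point; the intercept is free either way
        (the slab solution predicts ln(8/pi^2), not 0).
    """

    half_thickness_m: float = 1.5e-4
    mr_floor: float = 0.05
    include_t0: bool = True

    def __post_init__(self) -> None:
        if self.half_thickness_m <= 0:
            raise ValueError("half_thickness_m must be positive")
        if not 0 < self.mr_floor < 1:
            raise ValueError("mr_floor must lie in (0, 1)")


@dataclass
class DiffusionResult:
    temperature_C: float
    slope_per_s: float          # signed OLS slope of ln(MR) vs t [1/s]
    intercept: float
    deff_m2_s: float
    r2_line: float
    n_points: int

    @property
    def k1_per_s(self) -> float:
        return -self.slope_per_s


def deff_from_series(series: MoistureSeries,
                     settings: DiffusionSettings = DiffusionSettings()) -> DiffusionResult:
    """Extract Deff from one MR series via the ln(MR)-vs-time slope."""
    mask = series.mr > settings.mr_floor
    if not settings.include_t0:
        mask &= series.time_min > 0
    t_s = series.time_min[mask] * 60.0
    mr = series.mr[mask]
    if mr.size < 3:
        raise ValueError(
            f"only {mr.size} points with MR > {settings.mr_floor}; need >= 3 for the log regression"
        )
    res = stats.linregress(t_s, np.log(mr))
    if res.slope >= 0:
        raise ValueError("non-negative ln(MR) slope: series is not drying")
    k1 = -res.slope
    L = settings.half_thickness_m
    deff = 4.0 * L * L * k1 / np.pi**2
    return DiffusionResult(series.temperature_C, float(res.slope), float(res.intercept),
                           float(deff), float(res.rvalue**2), int(mr.size))


@dataclass
class ArrheniusResults:
    """Arrhenius fit over per-temperature diffusivities."""

    Ea_J_per_mol: float
    D0_m2_s: float
    r2: float
    n_temps: int

    @property
    def Ea_kJ_per_mol(self) -> float:
        return self.Ea_J_per_mol / 1000.0

    def predict(self, temperature_C) -> np.ndarray:
        T = np.asarray(temperature_C, dtype=float) + 273.15
        return self.D0_m2_s * np.exp(-self.Ea_J_per_mol / (R_J_PER_MOL_K * T))

    def summary(self) -> str:
        return (
            "Arrhenius fit of Deff(T)\n"
            f"  n_temps = {self.n_temps}\n"
            f"  Ea = {self.Ea_kJ_per_mol:.4g} kJ/mol\n"
            f"  D0 = {self.D0_m2_s:.4g} m^2/s\n"
            f"  R^2 = {self.r2:.6f}"
        )


class ArrheniusModel:
    """OLS of ln(Deff) on 1/(T + 273.15) over >= 3 distinct temperatures."""

    def __init__(self, points: list[tuple[float, float]]):
        temps = [p[0] for p in points]
        if len(set(temps)) < 3:
            raise ValueError("need >= 3 distinct temperatures for an Arrhenius fit")
        if len(set(temps)) != len(temps):
            raise ValueError("duplicate temperatures collapse the regression rank")
        if any(p[1] <= 0 for p in points):
            raise ValueError("all diffusivities must be positive")
        self.points = sorted(points)

    def fit(self) -> ArrheniusResults:
        T = np.array([p[0] for p in self.points]) + 273.15
        lnD = np.log([p[1] for p in self.points])
        if np.ptp(lnD) == 0.0:
            # flat limit: zero activation energy, D0 is the common value
            return ArrheniusResults(0.0, float(np.exp(lnD[0])), 1.0, len(self.points))
        res = stats.linregress(1.0 / T, lnD)
        return ArrheniusResults(
            Ea_J_per_mol=float(-res.slope * R_J_PER_MOL_K),
            D0_m2_s=float(np.exp(res.intercept)),
            r2=float(res.rvalue**2),
            n_temps=len(self.points),
        )


def arrhenius_fit(points) -> ArrheniusResults:
    """Functional wrapper: ``points`` is a sequence of (temperature_C, Deff)."""
    return ArrheniusModel(list(points)).fit()
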