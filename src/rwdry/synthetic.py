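"""In-silico refractance-window drying experiments.

Generates complete experiment bundles — drying curves, energy-meter series,
color/quality/rehydration panels — with the statistical structure the
analysis stages assume, so the whole pipeline is testable without any
laboratory data.

The drying curve is phenomenological: MR(t) = exp(-k(T) t^n) (Page form)
with the rate constant following an Arrhenius law in the water temperature,

    k(T) = k_ref exp[-(Ea_sim/R) (1/T - 1/T_ref)]    (T in kelvin),

plus additive Gaussian replicate noise on MR, clipped to [0, 1].  Defaults
emulate a bench-scale leaf-drying study: five water temperatures 50-90 C,
5-minute sampling, 80% wet-basis initial moisture, and drying times that
shrink from about 156 to 57 minutes as the temperature rises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R_J_PER_MOL_K
from .kinetics import DryingRun
from .quality import QualityRecord

__all__ = [
    "SyntheticConfig",
    "ExperimentBundle",
    "page_rate_at",
    "generate_drying_run",
    "generate_experiment",
    "write_bundle",
    "DEFAULT_QUALITY_MEANS",
    "DEFAULT_QUALITY_SDS",
]

MAX_SAMPLES = 10_000  # hard cap per run; guarantees termination

# Panel targets patterned on a bench mint RW-drying study: CIELAB color of
# fresh vs dried leaves, rehydration plateau, phenolics (mg GAE/100 g dw),
# flavonoids (mg QE/100 g dw), DPPH activity (%) and essential-oil yield (%).
DEFAULT_QUALITY_MEANS: dict[str, dict[str, float]] = {
    "fresh": {"L": 42.89, "a": -10.80, "b": 27.87, "tpc": 48.51, "tfc": 42.57, "aa_pct": 89.61},
    "50": {"L": 32.75, "a": -7.18, "b": 21.28, "rr": 3.79, "tpc": 31.18, "tfc": 26.52,
           "aa_pct": 58.55, "eo_pct": 0.82},
    "60": {"L": 35.46, "a": -8.50, "b": 23.35, "rr": 4.25, "tpc": 40.72, "tfc": 28.62,
           "aa_pct": 64.92, "eo_pct": 1.23},
    "70": {"L": 39.03, "a": -9.13, "b": 26.93, "rr": 4.50, "tpc": 46.42, "tfc": 36.81,
           "aa_pct": 75.31, "eo_pct": 1.93},
    "80": {"L": 37.77, "a": -8.72, "b": 25.32, "rr": 5.01, "tpc": 45.19, "tfc": 35.47,
           "aa_pct": 73.52, "eo_pct": 2.01},
    "90": {"L": 36.90, "a": -7.77, "b": 23.12, "rr": 4.72, "tpc": 38.52, "tfc": 31.34,
           "aa_pct": 67.50, "eo_pct": 1.73},
}

DEFAULT_QUALITY_SDS: dict[str, dict[str, float]] = {
    "fresh": {"L": 0.86, "a": 0.73, "b": 0.69, "tpc": 4.90, "tfc": 2.95, "aa_pct": 4.95},
    "50": {"L": 0.47, "a": 0.23, "b": 0.09, "rr": 0.06, "tpc": 0.70, "tfc": 0.46,
           "aa_pct": 0.90, "eo_pct": 0.03},
    "60": {"L": 0.56, "a": 0.24, "b": 0.09, "rr": 0.08, "tpc": 0.86, "tfc": 0.61,
           "aa_pct": 0.82, "eo_pct": 0.04},
    "70": {"L": 0.47, "a": 0.17, "b": 0.09, "rr": 0.05, "tpc": 0.40, "tfc": 0.82,
           "aa_pct": 1.41, "eo_pct": 0.07},
    "80": {"L": 0.41, "a": 0.19, "b": 0.09, "rr": 0.10, "tpc": 0.66, "tfc": 0.71,
           "aa_pct": 0.73, "eo_pct": 0.04},
    "90": {"L": 0.51, "a": 0.20, "b": 0.09, "rr": 0.08, "tpc": 0.70, "tfc": 0.78,
           "aa_pct": 0.70, "eo_pct": 0.01},
}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the emulated experiment: five water temperatures,
    triplicate runs, 5-minute sampling, 80% w.b. initial moisture, Page
    exponent 1.1 with k_ref = 0.0116 min^-n at 50 C and a simulated
    activation energy of 27 kJ/mol (drying times ~156 -> ~57 min over
    50 -> 90 C), runs terminated at MR <= 0.05.
    """

    temperatures_C: tuple[float, ...] = (50.0, 60.0, 70.0, 80.0, 90.0)
    replicates: int = 3
    interval_min: float = 5.0
    sample_mass_g: float = 50.0
    initial_moisture_wb_pct: float = 80.0
    page_n: float = 1.1
    k_ref_per_min: float = 0.0116
    Ea_sim_J_per_mol: float = 27_000.0
    T_ref_C: float = 50.0
    noise_sd_mr: float = 0.005
    mr_stop: float = 0.05
    seed: int = 0
    energy_kW: float = 0.09
    energy_jitter_rel: float = 0.02
    quality_means: dict = field(default_factory=lambda: DEFAULT_QUALITY_MEANS)
    quality_sds: dict = field(default_factory=lambda: DEFAULT_QUALITY_SDS)

    def __post_init__(self) -> None:
        t = tuple(self.temperatures_C)
        if len(t) == 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("temperatures must be non-empty and strictly increasing")
        if any(T <= -273.15 for T in t):
            raise ValueError("temperatures must exceed absolute zero")
        self.temperatures_C = t
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.initial_moisture_wb_pct < 100:
            raise ValueError("initial_moisture_wb_pct must lie in (0, 100)")
        if self.noise_sd_mr < 0:
            raise ValueError("noise_sd_mr must be >= 0")
        if not 0 < self.mr_stop < 1:
            raise ValueError("mr_stop must lie in (0, 1)")
        if self.interval_min <= 0 or self.sample_mass_g <= 0 or self.energy_kW < 0:
            raise ValueError("interval, sample mass must be positive; power non-negative")
        if self.page_n <= 0 or self.k_ref_per_min <= 0:
            raise ValueError("Page parameters must be positive")
        for panel in (self.quality_means, self.quality_sds):
            for label, metrics in panel.items():
                if panel is self.quality_sds and any(v < 0 for v in metrics.values()):
                    raise ValueError(f"negative SD in quality panel group {label!r}")

    @property
    def bone_dry_mass_g(self) -> float:
        return self.sample_mass_g * (1.0 - self.initial_moisture_wb_pct / 100.0)

    @property
    def x0_db(self) -> float:
        """Initial dry-basis moisture X0 = wb/(100 - wb)."""
        wb = self.initial_moisture_wb_pct
        return wb / (100.0 - wb)


@dataclass
class ExperimentBundle:
    """Everything one drying campaign produces."""

    drying_runs: list[DryingRun]
    energy_series: dict[str, pd.DataFrame]          # run_id -> (time_min, cum_kWh)
    color_panel: pd.DataFrame                       # label, replicate, L, a, b
    quality_panel: list[QualityRecord]
    rehydration_series: dict[str, pd.DataFrame]     # label -> (time_min, rehydrated_mass_g)

    def __post_init__(self) -> None:
        run_ids = {r.run_id for r in self.drying_runs}
        if set(self.energy_series) != run_ids:
            raise ValueError("need exactly one energy series per drying run")
        n_fresh = int((self.color_panel["label"] == "fresh").sum())
        if n_fresh < 1:
            raise ValueError("fresh color reference missing from the color panel")


def page_rate_at(temp_C: float, cfg: SyntheticConfig) -> float:
    """Arrhenius-tempered Page rate constant k(T), min^-n."""
    if temp_C <= -273.15:
        raise ValueError("non-physical temperature")
    T = temp_C + 273.15
    T_ref = cfg.T_ref_C + 273.15
    return cfg.k_ref_per_min * math.exp(-(cfg.Ea_sim_J_per_mol / R_J_PER_MOL_K) * (1.0 / T - 1.0 / T_ref))


def _run_seed(cfg: SyntheticConfig, temp_index: int, replicate: int) -> list[int]:
    # run-level stream derived from (master seed, temperature, replicate) so
    # adding replicates never perturbs existing ones
    return [int(cfg.seed) & 0x7FFFFFFF, temp_index, replicate]


def generate_drying_run(temp_C: float, cfg: SyntheticConfig,
                        seed=None, run_id: str | None = None) -> DryingRun:
    """One noisy drying run at ``temp_C``; ends at the first sample whose
    noiseless MR is <= cfg.mr_stop."""
    k = page_rate_at(temp_C, cfg)
    n = cfg.page_n
    t_end = (-math.log(cfg.mr_stop) / k) ** (1.0 / n)
    n_samples = int(math.ceil(t_end / cfg.interval_min)) + 1
    if n_samples > MAX_SAMPLES:
        raise RuntimeError(
            f"run at {temp_C} C needs {n_samples} samples to reach MR <= {cfg.mr_stop}, "
            f"exceeding the hard cap of {MAX_SAMPLES}"
        )
    t = np.arange(n_samples, dtype=float) * cfg.interval_min
    mr_true = np.exp(-k * np.power(t, n))
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    mr = mr_true.copy()
    if cfg.noise_sd_mr > 0:
        mr[1:] = mr[1:] + rng.normal(0.0, cfg.noise_sd_mr, size=mr.size - 1)
        mr = np.clip(mr, 0.0, 1.0)
    m_dry = cfg.bone_dry_mass_g
    mass = m_dry * (1.0 + mr * cfg.x0_db)
    return DryingRun(
        run_id=run_id or f"T{temp_C:g}",
        temperature_C=temp_C,
        time_min=t,
        mass_g=mass,
        bone_dry_mass_g=m_dry,
    )


def _energy_series(run: DryingRun, cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    dt_h = np.diff(run.time_min) / 60.0
    power = cfg.energy_kW * (1.0 + cfg.energy_jitter_rel * rng.standard_normal(dt_h.size))
    increments = np.maximum(power, 0.0) * dt_h
    cum = np.concatenate([[0.0], np.cumsum(increments)])
    return pd.DataFrame({"time_min": run.time_min, "cum_kWh": cum})


def _rehydration_curve(label: str, plateau: float, rng: np.random.Generator) -> pd.DataFrame:
    # three-phase shape: fast capillary uptake, slowdown, plateau from ~150 min
    t = np.array([0.0, 30.0, 60.0, 90.0, 120.0, 150.0])
    rr = 1.0 + (plateau - 1.0) * (1.0 - np.exp(-((t / 45.0) ** 1.5)))
    rr = np.maximum.accumulate(rr + np.concatenate([[0.0], rng.normal(0, 0.01, t.size - 1)]))
    dried_mass_g = 4.0
    return pd.DataFrame({"time_min": t, "rehydrated_mass_g": rr * dried_mass_g})


def generate_experiment(cfg: SyntheticConfig) -> ExperimentBundle:
    """Full campaign: one run per temperature x replicate plus panels."""
    runs: list[DryingRun] = []
    energy: dict[str, pd.DataFrame] = {}
    for ti, T in enumerate(cfg.temperatures_C):
        for rep in range(cfg.replicates):
            rid = f"T{T:g}_r{rep + 1}"
            seed = _run_seed(cfg, ti, rep)
            run = generate_drying_run(T, cfg, seed=seed, run_id=rid)
            runs.append(run)
            energy[rid] = _energy_series(run, cfg, np.random.default_rng(seed + [1]))

    color_rows, quality, rehydration = [], [], {}
    labels = ["fresh"] + [f"{T:g}" for T in cfg.temperatures_C]
    for li, label in enumerate(labels):
        means = cfg.quality_means.get(label, {})
        sds = cfg.quality_sds.get(label, {})
        for rep in range(cfg.replicates):
            rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 1000 + li, rep])

            def draw(key: str, lo: float | None = None, hi: float | None = None) -> float:
                if key not in means:
                    return math.nan
                v = rng.normal(means[key], sds.get(key, 0.0))
                if lo is not None:
                    v = max(v, lo)
                if hi is not None:
                    v = min(v, hi)
                return v

            color_rows.append({
                "label": label, "replicate": rep + 1,
                "L": draw("L", 0.0, 100.0), "a": draw("a"), "b": draw("b"),
            })
            quality.append(QualityRecord(
                label=label, rr=draw("rr", 1.0), tpc=draw("tpc", 0.0),
                tfc=draw("tfc", 0.0), aa_pct=draw("aa_pct", 0.0, 100.0),
                eo_pct=draw("eo_pct", 0.0),
            ))
        if label != "fresh" and "rr" in means:
            rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 2000 + li])
            rehydration[label] = _rehydration_curve(label, means["rr"], rng)

    return ExperimentBundle(runs, energy, pd.DataFrame(color_rows), quality, rehydration)


# ---------------------------------------------------------------------------
# tidy CSV output

_FLOAT_FMT = "%.10g"


def write_bundle(bundle: ExperimentBundle, outdir) -> dict[str, str]:
    """Write the bundle as tidy CSV files; returns {name: path}."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = []
    for run in bundle.drying_runs:
        for t, m in zip(run.time_min, run.mass_g):
            rows.append({"run_id": run.run_id, "temperature_C": run.temperature_C,
                         "time_min": t, "mass_g": m, "bone_dry_mass_g": run.bone_dry_mass_g})
    paths["drying_runs"] = str(out / "drying_runs.csv")
    pd.DataFrame(rows).to_csv(paths["drying_runs"], index=False, float_format=_FLOAT_FMT)

    erows = []
    for rid, df in bundle.energy_series.items():
        for t, e in zip(df["time_min"], df["cum_kWh"]):
            erows.append({"run_id": rid, "time_min": t, "cum_kWh": e})
    paths["energy"] = str(out / "energy.csv")
    pd.DataFrame(erows).to_csv(paths["energy"], index=False, float_format=_FLOAT_FMT)

    paths["color_panel"] = str(out / "color_panel.csv")
    bundle.color_panel.to_csv(paths["color_panel"], index=False, float_format=_FLOAT_FMT)

    qrows = [{"label": q.label, "rr": q.rr, "tpc": q.tpc, "tfc": q.tfc,
              "aa_pct": q.aa_pct, "eo_pct": q.eo_pct} for q in bundle.quality_panel]
    paths["quality_panel"] = str(out / "quality_panel.csv")
    pd.DataFrame(qrows).to_csv(paths["quality_panel"], index=False, float_format=_FLOAT_FMT)

    rrows = []
    for label, df in bundle.rehydration_series.items():
        for t, m in zip(df["time_min"], df["rehydrated_mass_g"]):
            rrows.append({"label": label, "time_min": t, "rehydrated_mass_g": m})
    paths["rehydration"] = str(out / "rehydration.csv")
    pd.DataFrame(rrows).to_csv(paths["rehydration"], index=False, float_format=_FLOAT_FMT)
    return paths


def read_drying_runs(path) -> list[DryingRun]:
    """Read a tidy drying-run CSV back into DryingRun objects."""
    df = pd.read_csv(path)
    runs = []
    for rid, g in df.groupby("run_id", sort=False):
        g = g.sort_values("time_min")
        runs.append(DryingRun(
            run_id=str(rid),
            temperature_C=float(g["temperature_C"].iloc[0]),
            time_min=g["time_min"].to_numpy(),
            mass_g=g["mass_g"].to_numpy(),
            bone_dry_mass_g=float(g["bone_dry_mass_g"].iloc[0]),
        ))
    return runs
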