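"""Reference summary tables from a published bench-scale mint
refractance-window drying experiment (means +/- SD at water temperatures
50-90 C).  These ship with the package so the diffusivity/thermodynamic/
emission chain can be exercised on real printed values; the raw time series
behind them were never deposited, so per-run quantities must come from the
synthetic generator or user CSVs.
"""

from importlib import resources

import pandas as pd

__all__ = [
    "load_drying_summary",
    "load_thermo_summary",
    "load_color_summary",
    "load_quality_summary",
    "load_model_stats",
    "load_ann_topologies",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open("rb") as fh:
        return pd.read_csv(fh)


def load_drying_summary() -> pd.DataFrame:
    """Per-temperature drying time, Deff, SEC and CO2/NOx intensities."""
    return _load("drying_summary.csv")


def load_thermo_summary() -> pd.DataFrame:
    """Per-temperature activation enthalpy/entropy/Gibbs energy."""
    return _load("thermo_summary.csv")


def load_color_summary() -> pd.DataFrame:
    """CIELAB color panel (fresh reference plus five dried groups)."""
    return _load("color_summary.csv")


def load_quality_summary() -> pd.DataFrame:
    """Rehydration, phenolics, flavonoids, DPPH activity, essential oil."""
    return _load("quality_summary.csv")


def load_model_stats() -> pd.DataFrame:
    """Reported thin-layer model R^2/MSE per temperature."""
    return _load("model_stats.csv")


def load_ann_topologies() -> pd.DataFrame:
    """Reported best MLP topologies with test MSE/R^2 and epochs."""
    return _load("ann_topologies.csv")
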