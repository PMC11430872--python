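"""Post-drying quality metrics: CIELAB color, rehydration, antioxidant
activity, and panel summaries.

Color difference uses the Euclidean CIELAB form
dE = sqrt(dL*^2 + da*^2 + db*^2) against the fresh reference, and Chroma is
the radial saturation C = sqrt(a*^2 + b*^2).  Rehydration ratio RR = Wr/Wd
indexes structural quality; DPPH antioxidant activity is the percent drop
in radical absorbance caused by the extract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ColorReading",
    "QualityRecord",
    "delta_e",
    "chroma",
    "rehydration_ratio",
    "antioxidant_pct",
    "summarize_panel",
]


@dataclass(frozen=True)
class ColorReading:
    L_star: float
    a_star: float
    b_star: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.L_star <= 100:
            raise ValueError("L* must lie in [0, 100]")


@dataclass
class QualityRecord:
    """One replicate of the per-temperature quality panel."""

    label: str                      # "fresh" or a temperature label like "70"
    rr: float = math.nan            # rehydration ratio
    tpc: float = math.nan           # total phenolics, mg GAE/100 g dw
    tfc: float = math.nan           # total flavonoids, mg QE/100 g dw
    aa_pct: float = math.nan        # DPPH antioxidant activity, %
    eo_pct: float = math.nan        # essential-oil yield, %


def delta_e(fresh: ColorReading, dried: ColorReading) -> float:
    """Euclidean CIELAB color difference; symmetric in its arguments."""
    return math.sqrt(
        (fresh.L_star - dried.L_star) ** 2
        + (fresh.a_star - dried.a_star) ** 2
        + (fresh.b_star - dried.b_star) ** 2
    )


def chroma(a_star: float, b_star: float) -> float:
    """Chroma C = sqrt(a*^2 + b*^2) >= 0."""
    return math.hypot(a_star, b_star)


def rehydration_ratio(rehydrated_mass_g: float, dried_mass_g: float) -> float:
    """RR = Wr / Wd (tracked per soak time to form the rehydration curve)."""
    if dried_mass_g <= 0:
        raise ValueError("dried mass must be positive")
    if rehydrated_mass_g < 0:
        raise ValueError("rehydrated mass cannot be negative")
    return rehydrated_mass_g / dried_mass_g


def antioxidant_pct(a_sample: float, a_control: float) -> float:
    """DPPH activity AA% = 100 (1 - A_sample/A_control).

    A sample darker than the control yields a negative value; it is
    reported as-is with a warning rather than clipped.
    """
    if a_control <= 0:
        raise ValueError("control absorbance must be positive")
    if a_sample < 0:
        raise ValueError("sample absorbance cannot be negative")
    aa = 100.0 * (1.0 - a_sample / a_control)
    if aa < 0:
        warnings.warn("sample absorbance exceeds control: negative antioxidant activity",
                      stacklevel=2)
    return aa


_PANEL_COLS = ("rr", "tpc", "tfc", "aa_pct", "eo_pct")


def summarize_panel(records: list[QualityRecord],
                    reference_label: str | None = None) -> pd.DataFrame:
    """Per-group mean +/- SD table with percent-change columns vs a reference.

    SD is the sample standard deviation (ddof=1; 0 for singleton groups).
    Percent change uses the drop convention (positive = decrease from the
    reference group).
    """
    if not records:
        raise ValueError("empty panel")
    df = pd.DataFrame([{"label": r.label, **{c: getattr(r, c) for c in _PANEL_COLS}}
                       for r in records])
    if (df.groupby("label").size() < 1).any():
        raise ValueError("every group needs at least one record")
    agg = df.groupby("label", sort=False).agg(["mean", lambda s: s.std(ddof=1)])
    agg.columns = [f"{col}_{'sd' if name == '<lambda_0>' else name}" for col, name in agg.columns]
    agg = agg.fillna({c: 0.0 for c in agg.columns if c.endswith("_sd")})
    if reference_label is not None:
        if reference_label not in agg.index:
            raise ValueError(f"reference label {reference_label!r} not present in the panel")
        ref = agg.loc[reference_label]
        for c in _PANEL_COLS:
            with np.errstate(divide="ignore", invalid="ignore"):
                agg[f"{c}_pct_change"] = 100.0 * (ref[f"{c}_mean"] - agg[f"{c}_mean"]) / ref[f"{c}_mean"]
    return agg.reset_index()
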