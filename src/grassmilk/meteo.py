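"""Temperature–humidity index and probability–meteorology correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = ["compute_thi", "correlate_with_meteo", "METEO_TRAITS"]

METEO_TRAITS = ("temperature", "humidity", "cloud", "rain", "thi")


def compute_thi(temperature, humidity):
    """Temperature–humidity index for dairy cattle.

    THI = 0.8·T + (H/100)·(T − 14.4) + 46.4, with T the ambient temperature
    in °C and H the relative humidity in percent.  At T = 14.4 °C the
    humidity term vanishes.  Accepts scalars or arrays (broadcast).
    """
    t = np.asarray(temperature, dtype=float)
    h = np.asarray(humidity, dtype=float)
    if np.any((h < 0) | (h > 100)):
        raise InputError("humidity must lie in [0, 100] %")
    thi = 0.8 * t + (h / 100.0) * (t - 14.4) + 46.4
    if np.ndim(temperature) == 0 and np.ndim(humidity) == 0:
        return float(thi)
    return thi


def correlate_with_meteo(curve: pd.DataFrame, meteo: pd.DataFrame) -> pd.Series:
    """Pearson correlation of a monthly probability curve with each meteo trait.

    ``curve`` must carry ``year, month, mean_probability``; the series are
    aligned on exact (year, month) keys, non-overlapping cells are dropped
    pairwise, and years are pooled into one series per trait.
    """
    required = {"year", "month", "mean_probability"}
    if not required.issubset(curve.columns):
        raise InputError(f"curve must have columns {sorted(required)}")
    merged = curve.merge(meteo, on=["year", "month"], how="inner")
    if len(merged) < 3:
        raise InputError(
            f"need >= 3 overlapping (year, month) cells, got {len(merged)}"
        )
    out = {}
    for trait in METEO_TRAITS:
        if trait in merged.columns:
            out[trait] = float(
                stats.pearsonr(merged["mean_probability"], merged[trait]).statistic
            )
    return pd.Series(out, name="pearson_r")
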