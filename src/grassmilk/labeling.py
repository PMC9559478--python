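"""Month-derived grazing labels and modelling subsets.

In the study region nearly all herds graze from April to September, with
full grazing roughly May–August.  Absent grazing calendars, the calendar
month of the milk test serves as an indirect label.  Three nested labelling
schemes trade coverage against label purity:

========  ==================  ====================
scheme    GRASS months        NOGRASS months
========  ==================  ====================
1         May–Aug             Nov–Feb
2         Jun–Aug             Dec–Feb
3         Jul–Aug             Jan–Feb
========  ==================  ====================

Every other month is OTHERS (feeding-transition period) and is excluded
from model fitting; scheme 3's sets are subsets of scheme 2's, which are
subsets of scheme 1's.  GRASS is the positive class throughout, so
sensitivity reads as GRASS recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateLabelError, InputError

__all__ = [
    "GrassScheme",
    "SCHEMES",
    "assign_grass_label",
    "label_records",
    "build_modeling_subset",
    "split_by_farm",
    "GRASS",
    "NOGRASS",
    "OTHERS",
]

GRASS = "GRASS"
NOGRASS = "NOGRASS"
OTHERS = "OTHERS"


@dataclass(frozen=True)
class GrassScheme:
    scheme_id: int
    grass_months: frozenset[int]
    nograss_months: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.grass_months) != len(self.nograss_months):
            raise InputError("GRASS and NOGRASS month sets must be the same size")
        if self.grass_months & self.nograss_months:
            raise InputError("GRASS and NOGRASS month sets overlap")


SCHEMES: dict[int, GrassScheme] = {
    1: GrassScheme(1, frozenset({5, 6, 7, 8}), frozenset({11, 12, 1, 2})),
    2: GrassScheme(2, frozenset({6, 7, 8}), frozenset({12, 1, 2})),
    3: GrassScheme(3, frozenset({7, 8}), frozenset({1, 2})),
}


def _as_scheme(scheme: int | GrassScheme) -> GrassScheme:
    if isinstance(scheme, GrassScheme):
        return scheme
    try:
        return SCHEMES[int(scheme)]
    except (KeyError, ValueError):
        raise InputError(f"unknown labelling scheme {scheme!r}") from None


def assign_grass_label(month: int, scheme: int | GrassScheme) -> str:
    """Modality (GRASS / NOGRASS / OTHERS) of a test month under a scheme."""
    sch = _as_scheme(scheme)
    m = int(month)
    if not 1 <= m <= 12:
        raise InputError(f"month must lie in 1..12, got {month}")
    if m in sch.grass_months:
        return GRASS
    if m in sch.nograss_months:
        return NOGRASS
    return OTHERS


def label_records(records: pd.DataFrame, scheme: int | GrassScheme) -> pd.DataFrame:
    """Append a ``modality`` column derived from the ``month`` column."""
    sch = _as_scheme(scheme)
    months = records["month"].to_numpy()
    if np.any((months < 1) | (months > 12)):
        raise InputError("month values must lie in 1..12")
    modality = np.full(len(records), OTHERS, dtype=object)
    modality[np.isin(months, list(sch.grass_months))] = GRASS
    modality[np.isin(months, list(sch.nograss_months))] = NOGRASS
    out = records.copy()
    out["modality"] = modality
    return out


def build_modeling_subset(labeled: pd.DataFrame) -> pd.DataFrame:
    """Drop OTHERS rows and attach the binary target.

    Returns the retained rows in their original order with an integer
    ``target`` column (GRASS = 1, NOGRASS = 0).  Raises
    :class:`DegenerateLabelError` if either class would be empty.
    """
    if "modality" not in labeled.columns:
        raise InputError("records must be labelled first (no 'modality' column)")
    subset = labeled[labeled["modality"] != OTHERS].copy()
    n_grass = int((subset["modality"] == GRASS).sum())
    n_nograss = int((subset["modality"] == NOGRASS).sum())
    if n_grass == 0 or n_nograss == 0:
        raise DegenerateLabelError(
            f"degenerate labels: {n_grass} GRASS and {n_nograss} NOGRASS rows"
        )
    subset["target"] = (subset["modality"] == GRASS).astype(int)
    return subset


def split_by_farm(
    records: pd.DataFrame, calibration_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into calibration and validation sets by farm.

    Farms — never individual records — are randomly assigned, so no herd
    contributes to both sets.  ``round(fraction * n_farms)`` farms go to
    calibration.
    """
    if not 0.0 < calibration_fraction < 1.0:
        raise InputError("calibration_fraction must lie in (0, 1)")
    farms = np.array(sorted(records["farm_id"].unique()))
    if len(farms) < 2:
        raise InputError("need at least 2 farms to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(farms))
    n_cal = int(round(calibration_fraction * len(farms)))
    n_cal = min(max(n_cal, 1), len(farms) - 1)
    cal_farms = set(farms[order[:n_cal]])
    in_cal = records["farm_id"].isin(cal_farms)
    return records[in_cal].copy(), records[~in_cal].copy()
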