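"""CSV readers/writers for trait, meteorology and result tables.

All artefacts are plain UTF-8 CSV with a single header row and '.' decimal
separators.  Files written by the pipeline start with a ``#`` comment line
recording the configuration hash and the root seed, so any output can be
traced to the exact run that produced it; readers skip such comments.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import SchemaError

__all__ = ["write_table", "read_table", "read_trait_table", "read_meteo_table"]

logger = logging.getLogger(__name__)

ID_COLUMNS = ("farm_id", "year", "month")
METEO_COLUMNS = ("year", "month", "temperature", "humidity", "cloud", "rain", "thi")


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    seed: int | None = None,
) -> Path:
    """Write a DataFrame as CSV, with an optional provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash is not None or seed is not None:
            fh.write(f"# grassmilk config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV (skipping ``#`` comments) and check required columns."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(missing, message=f"{path}: missing column(s): {', '.join(missing)}")
    return df


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a herd trait table (``farm_id, year, month, <traits>...``).

    Trait columns are coerced to numeric; rows with unparseable values are
    rejected, and their 1-based file line numbers logged.  An empty file
    (header only) yields an empty frame with a warning.
    """
    df = read_table(path, required=ID_COLUMNS)
    if len(df) == 0:
        logger.warning("%s: empty trait table (header only)", path)
        return df
    value_cols = [c for c in df.columns if c not in ("farm_id", "modality")]
    coerced = df.copy()
    for col in value_cols:
        coerced[col] = pd.to_numeric(coerced[col], errors="coerce")
    bad = coerced[value_cols].isna().any(axis=1) & ~df[value_cols].isna().any(axis=1)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering (comment
        # lines, if any, shift this; good enough for diagnostics)
        lines = (coerced.index[bad] + 2).tolist()
        logger.warning(
            "%s: rejected %d unparseable row(s) at line(s) %s", path, bad.sum(), lines
        )
        coerced = coerced[~bad]
    return coerced.reset_index(drop=True)


def read_meteo_table(path: str | Path) -> pd.DataFrame:
    """Read a monthly meteorology table."""
    return read_table(path, required=METEO_COLUMNS)
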