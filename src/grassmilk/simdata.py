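"""Seeded synthetic meteorology, latent grass fractions and milk records.

The generator emulates a temperate-maritime dairy region (southern Belgium)
where herds graze roughly April–September with a full-grass plateau in
June–August, and milk is sampled as a herd bulk tank once per month.  One
monthly meteorology series applies to every farm (the real counterpart is a
single-city weather record).

The data-generating model, per record (farm f, year y, month m):

    g_{fym}  = latent grass fraction in [0, 1]
             = amplitude_f * ramp(m; width) * thi_mod(THI_ym), 0 in Dec-Feb
    x_{j}    = baseline_j * (1 + (mult_j - 1) * g_{fym}) + eps_j

with eps_j Gaussian of SD noise_sd_j; the 31 fatty-acid residuals share a
common factor (equicorrelation ``fa_noise_rho``) because in the real
pipeline they are predicted from overlapping spectral regions.

g is stored in the output (column ``latent_g``) purely as ground truth for
tests and recovery checks; no model stage may read it.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .meteo import compute_thi
from .schema import (
    ARCHETYPE_DEFAULTS,
    FA_TRAITS,
    LCFA_GROUP,
    FarmArchetype,
    TraitSchema,
    default_schema,
    make_archetype,
)

__all__ = [
    "simulate_meteo",
    "grass_fraction",
    "generate_dataset",
    "make_farms",
    "DEFAULT_ARCHETYPE_MIX",
]

FIRST_YEAR = 2016

#: default cohort composition; most Walloon herds graze, a small share run
#: intensively, and a sliver of bulk tanks contain skimmed milk.
DEFAULT_ARCHETYPE_MIX: dict[str, float] = {
    "intensive": 0.20,
    "intermediate": 0.35,
    "extensive": 0.40,
    "skimmed": 0.05,
}

# annual cycles: temperature peaks in July, humidity/cloud are anti-phased
_TEMP_MEAN, _TEMP_AMP, _TEMP_SD = 10.0, 8.0, 1.5
_HUM_MEAN, _HUM_AMP, _HUM_SD = 78.0, 10.0, 3.0
_CLOUD_MEAN, _CLOUD_AMP, _CLOUD_SD = 62.0, 14.0, 5.0
_RAIN_MEAN, _RAIN_SD = 70.0, 18.0

# grass-season geometry (month units)
_SPRING_MID = 4.3       # mid-point of the turn-out ramp
_AUTUMN_MID = 9.8       # mid-point of the housing ramp
_WINTER_MONTHS = (12, 1, 2)

# THI modulation of the summer plateau: warmer months push the realised
# grass fraction up, cold ones down, within +-15 %.
_THI_REF, _THI_SCALE, _THI_GAIN = 60.0, 20.0, 0.15
_THI_MOD_LO, _THI_MOD_HI = 0.85, 1.15

_SKIMMED_FAT_MEAN, _SKIMMED_FAT_SD = 0.25, 0.05
_SKIMMED_MILK_YIELD = 28.3


def _substream(seed: int, *tags: str) -> np.random.Generator:
    """Independent RNG substream from the root seed and stable string tags.

    Tags are hashed with SHA-256, so per-farm streams do not depend on how
    many farms exist or in which order they are generated.
    """
    entropy = [int(seed)]
    for tag in tags:
        digest = hashlib.sha256(tag.encode("utf-8")).digest()
        entropy.append(int.from_bytes(digest[:8], "little"))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_meteo(n_years: int, seed: int, first_year: int = FIRST_YEAR) -> pd.DataFrame:
    """Simulate a monthly meteorology table for ``n_years`` calendar years.

    Returns a DataFrame with columns
    ``year, month, temperature, humidity, cloud, rain, thi``; temperature
    follows a sinusoid peaking in July with seeded noise, humidity and cloud
    cover are anti-phased (peaking in winter), and THI is derived from
    temperature and humidity.
    """
    if n_years < 1:
        raise InputError("n_years must be >= 1")
    rng = _substream(seed, "meteo")
    years = np.repeat(np.arange(first_year, first_year + n_years), 12)
    months = np.tile(np.arange(1, 13), n_years)
    n = len(months)
    # cos(2*pi*(m-7)/12) peaks at m = 7 (July)
    summer_phase = np.cos(2 * np.pi * (months - 7) / 12.0)
    temperature = _TEMP_MEAN + _TEMP_AMP * summer_phase + rng.normal(0, _TEMP_SD, n)
    humidity = np.clip(
        _HUM_MEAN - _HUM_AMP * summer_phase + rng.normal(0, _HUM_SD, n), 0, 100
    )
    cloud = np.clip(
        _CLOUD_MEAN - _CLOUD_AMP * summer_phase + rng.normal(0, _CLOUD_SD, n), 0, 100
    )
    rain = np.maximum(0.0, _RAIN_MEAN + rng.normal(0, _RAIN_SD, n))
    thi = compute_thi(temperature, humidity)
    return pd.DataFrame(
        {
            "year": years,
            "month": months,
            "temperature": temperature,
            "humidity": humidity,
            "cloud": cloud,
            "rain": rain,
            "thi": thi,
        }
    )


def _seasonal_ramp(month: np.ndarray | float, transition_width: float) -> np.ndarray:
    """Smooth 0→1→0 seasonal profile: logistic turn-out and housing ramps."""
    m = np.asarray(month, dtype=float)
    w = transition_width / 4.0  # logistic scale so the ramp spans ~width months
    up = 1.0 / (1.0 + np.exp(-(m - _SPRING_MID) / w))
    down = 1.0 / (1.0 + np.exp((m - _AUTUMN_MID) / w))
    return up * down


def grass_fraction(
    archetype: FarmArchetype,
    meteo: pd.Series | pd.DataFrame,
    transition_width: float = 1.5,
) -> np.ndarray | float:
    """Latent fraction of fresh grass in the ration for the given month(s).

    Zero in December–February (herds are housed), logistic ramps through
    spring and autumn, and a plateau near ``grass_amplitude`` in June–August
    whose height is modulated by the month's temperature–humidity index
    (warm months sustain more grass growth and intake).
    """
    if isinstance(meteo, pd.DataFrame):
        months = meteo["month"].to_numpy()
        thi = meteo["thi"].to_numpy()
        scalar = False
    else:
        months = np.asarray([meteo["month"]])
        thi = np.asarray([meteo["thi"]], dtype=float)
        scalar = True
    if np.any((months < 1) | (months > 12)):
        raise InputError("month must lie in 1..12")
    ramp = _seasonal_ramp(months, transition_width)
    thi_mod = np.clip(
        1.0 + _THI_GAIN * (thi - _THI_REF) / _THI_SCALE, _THI_MOD_LO, _THI_MOD_HI
    )
    g = np.clip(archetype.grass_amplitude * ramp * thi_mod, 0.0, 1.0)
    g[np.isin(months, _WINTER_MONTHS)] = 0.0
    return float(g[0]) if scalar else g


def make_farms(
    n_farms: int,
    archetype_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> list[FarmArchetype]:
    """Assign archetypes to ``n_farms`` farms.

    Counts follow the mix proportions deterministically (largest-remainder
    rounding); which farm gets which archetype is a seeded permutation.
    """
    mix = dict(DEFAULT_ARCHETYPE_MIX if archetype_mix is None else archetype_mix)
    if n_farms < 1:
        raise InputError("n_farms must be >= 1")
    unknown = set(mix) - set(ARCHETYPE_DEFAULTS)
    if unknown:
        raise ConfigurationError(f"unknown archetypes in mix: {sorted(unknown)}")
    total = sum(mix.values())
    if not np.isclose(total, 1.0):
        raise ConfigurationError(f"archetype mix must sum to 1 (got {total})")
    names = sorted(mix)
    raw = np.array([mix[a] * n_farms for a in names])
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n_farms - counts.sum()]:
        counts[i] += 1
    kinds: list[str] = []
    for name, c in zip(names, counts):
        kinds.extend([name] * int(c))
    order = _substream(seed, "farm-archetypes").permutation(n_farms)
    width = max(4, len(str(n_farms)))
    return [
        make_archetype(f"F{idx + 1:0{width}d}", kinds[order[idx]])
        for idx in range(n_farms)
    ]


def _farm_records(
    farm: FarmArchetype,
    meteo: pd.DataFrame,
    schema: TraitSchema,
    seed: int,
    transition_width: float,
    fa_noise_rho: float,
) -> pd.DataFrame:
    rng = _substream(seed, "farm", farm.farm_id)
    n = len(meteo)
    g = np.asarray(grass_fraction(farm, meteo, transition_width))
    # Skimmed submissions: the fat extraction alters the milk matrix, so the
    # analysed traits no longer reflect the herd's feeding — their mean
    # structure carries no grazing signal (latent_g is still recorded).
    g_expressed = np.zeros_like(g) if farm.skimmed_flag else g

    names = schema.names
    baselines = np.array([t.baseline_mean for t in schema.traits])
    sds = np.array([t.noise_sd for t in schema.traits])
    mults = np.array([t.grass_multiplier for t in schema.traits])

    mean = baselines[None, :] * (1.0 + (mults - 1.0)[None, :] * g_expressed[:, None])

    is_fa = np.array([name in FA_TRAITS for name in names])
    z = rng.standard_normal((n, len(names)))
    if fa_noise_rho > 0:
        common = rng.standard_normal(n)
        z[:, is_fa] = (
            np.sqrt(fa_noise_rho) * common[:, None]
            + np.sqrt(1 - fa_noise_rho) * z[:, is_fa]
        )
    values = mean + sds[None, :] * z

    lcfa_members = [t for t in LCFA_GROUP if t in names]
    if farm.winter_lcfa_offset != 0.0 and lcfa_members:
        # extensive winter rations (hay/silage rich in C18 sources) push the
        # long-chain traits up when the herd is off grass
        lcfa_base = schema["LCFA"].baseline_mean
        winter_weight = 1.0 - g  # strongest when no grass
        for t in lcfa_members:
            j = names.index(t)
            values[:, j] += (
                farm.winter_lcfa_offset * baselines[j] / lcfa_base * winter_weight
            )

    if farm.skimmed_flag and "fat" in names:
        fat_idx = names.index("fat")
        skim_fat = np.maximum(
            0.05, _SKIMMED_FAT_MEAN + rng.normal(0, _SKIMMED_FAT_SD, n)
        )
        scale = skim_fat / schema["fat"].baseline_mean
        fa_idx = np.flatnonzero(is_fa)
        values[:, fa_idx] *= scale[:, None]
        values[:, fat_idx] = skim_fat
        if "milk_yield" in names:
            values[:, names.index("milk_yield")] = _SKIMMED_MILK_YIELD + rng.normal(
                0, schema["milk_yield"].noise_sd, n
            )

    out = pd.DataFrame(values, columns=names)
    out.insert(0, "month", meteo["month"].to_numpy())
    out.insert(0, "year", meteo["year"].to_numpy())
    out.insert(0, "farm_id", farm.farm_id)
    out["latent_g"] = g
    return out


def generate_dataset(
    n_farms: int,
    n_years: int,
    archetype_mix: dict[str, float] | None = None,
    schema: TraitSchema | None = None,
    seed: int = 0,
    transition_width: float = 1.5,
    fa_noise_rho: float = 0.3,
    meteo: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[FarmArchetype]]:
    """Generate the full synthetic herd dataset.

    Returns ``(records, meteo, farms)`` where ``records`` has one row per
    farm-month (``n_farms * n_years * 12`` rows) with columns
    ``farm_id, year, month, <48 traits>, latent_g``.

    Each farm draws from its own RNG substream keyed by ``(seed, farm_id)``,
    so enlarging the cohort never perturbs existing farms' records.
    """
    if schema is None:
        schema = default_schema()
    if len(schema) == 0:
        raise ConfigurationError("empty trait schema")
    if n_years < 1:
        raise InputError("n_years must be >= 1")
    if meteo is None:
        meteo = simulate_meteo(n_years, seed)
    farms = make_farms(n_farms, archetype_mix, seed)
    frames = [
        _farm_records(farm, meteo, schema, seed, transition_width, fa_noise_rho)
        for farm in farms
    ]
    records = pd.concat(frames, ignore_index=True)
    return records, meteo, farms
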