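"""Trait schema for herd bulk-milk composition records.

The predictor set mirrors the 48 milk traits routinely predicted from
standardized FT-MIR spectra in Walloon milk recording: the four traits the
spectrometer reports directly (fat, protein, urea, lactose), milk yield,
31 fatty-acid traits expressed in g/dL of milk, lactoferrin, six protein
fractions and five minerals.

Each trait carries

* ``baseline_mean`` — its expected value for a herd on a winter total mixed
  ration (no fresh grass).  These are plausible bulk-milk values for
  Holstein-dominated herds; no reference herd publishes its means, so they
  are documented defaults, not measurements.
* ``noise_sd`` — the residual standard deviation of the simulated value.
  For the 44 equation-predicted traits this defaults to the published RMSE
  of the corresponding FT-MIR prediction equation, so the simulated
  prediction error is realistic; for the four direct traits a small
  instrument-level SD is used.
* ``grass_multiplier`` — the multiplicative shift of the trait mean when the
  herd is on full fresh-grass feeding (latent grass fraction g = 1).  The
  anchor effects are the established pasture signatures: C18:3 cis-9,12,15
  roughly fourfold up, conjugated linoleic acid (C18:2 cis-9, trans-11)
  twofold up, fat and protein about +5 %, milk volume down to ~62 %,
  long-chain fatty acids up, short- and medium-chain fatty acids down, and
  Ca up / P down among the minerals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

__all__ = [
    "TraitSpec",
    "TraitSchema",
    "FarmArchetype",
    "default_schema",
    "FA_TRAITS",
    "N_PREDICTORS",
]

N_PREDICTORS = 48


@dataclass(frozen=True)
class TraitSpec:
    """One predictor trait: identity, unit and simulation parameters."""

    name: str
    unit: str
    baseline_mean: float
    noise_sd: float
    grass_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError(f"trait {self.name!r}: noise_sd must be > 0")
        if self.grass_multiplier <= 0:
            raise ConfigurationError(
                f"trait {self.name!r}: grass_multiplier must be > 0"
            )


# 31 fatty-acid traits, generated on the g/dL-of-milk scale with correlated
# residuals (they are predicted from overlapping spectral regions in the
# real pipeline, so their errors co-move).
FA_TRAITS: tuple[str, ...] = (
    "C4_0", "C6_0", "C8_0", "C10_0", "C12_0", "C14_0", "C14_1_cis",
    "C16_0", "C16_1_cis", "C17_0", "C18_0",
    "C18_1_total", "C18_1_trans", "C18_1_cis", "C18_1_cis9",
    "C18_2_total", "C18_2_cis9_cis12", "C18_2_cis9_trans11",
    "C18_3_cis9_cis12_cis15",
    "SFA", "MUFA", "PUFA", "UFA", "SCFA", "MCFA", "LCFA",
    "branched_FA", "omega3", "omega6", "odd_FA", "trans_FA",
)

# Traits counted as "long-chain" for the extensive-winter-ration offset.
LCFA_GROUP: tuple[str, ...] = (
    "LCFA", "C18_0", "C18_1_total", "C18_1_cis", "C18_1_cis9", "trans_FA",
)

_DEFAULT_TRAITS: tuple[TraitSpec, ...] = (
    # name, unit, winter baseline, residual SD, multiplier at full grass
    TraitSpec("fat", "g/100 g", 4.05, 0.05, 1.05),
    TraitSpec("protein", "g/100 g", 3.40, 0.04, 1.05),
    TraitSpec("urea", "mg/dL", 24.0, 1.5, 1.25),
    TraitSpec("lactose", "g/100 g", 4.60, 0.04, 1.00),
    TraitSpec("milk_yield", "kg/day", 26.0, 3.48, 0.62),
    TraitSpec("C4_0", "g/dL milk", 0.130, 0.008, 1.05),
    TraitSpec("C6_0", "g/dL milk", 0.090, 0.006, 0.92),
    TraitSpec("C8_0", "g/dL milk", 0.050, 0.004, 0.90),
    TraitSpec("C10_0", "g/dL milk", 0.115, 0.010, 0.85),
    TraitSpec("C12_0", "g/dL milk", 0.135, 0.011, 0.85),
    TraitSpec("C14_0", "g/dL milk", 0.455, 0.030, 0.90),
    TraitSpec("C14_1_cis", "g/dL milk", 0.040, 0.008, 0.95),
    TraitSpec("C16_0", "g/dL milk", 1.300, 0.091, 1.06),
    TraitSpec("C16_1_cis", "g/dL milk", 0.060, 0.013, 1.05),
    TraitSpec("C17_0", "g/dL milk", 0.022, 0.003, 1.30),
    TraitSpec("C18_0", "g/dL milk", 0.380, 0.056, 1.15),
    TraitSpec("C18_1_total", "g/dL milk", 0.900, 0.060, 1.25),
    TraitSpec("C18_1_trans", "g/dL milk", 0.095, 0.025, 1.60),
    TraitSpec("C18_1_cis", "g/dL milk", 0.800, 0.063, 1.20),
    TraitSpec("C18_1_cis9", "g/dL milk", 0.750, 0.061, 1.20),
    TraitSpec("C18_2_total", "g/dL milk", 0.110, 0.014, 1.20),
    TraitSpec("C18_2_cis9_cis12", "g/dL milk", 0.060, 0.011, 0.85),
    TraitSpec("C18_2_cis9_trans11", "g/dL milk", 0.015, 0.010, 2.00),
    TraitSpec("C18_3_cis9_cis12_cis15", "g/dL milk", 0.012, 0.004, 4.00),
    TraitSpec("SFA", "g/dL milk", 2.900, 0.072, 0.93),
    TraitSpec("MUFA", "g/dL milk", 1.050, 0.059, 1.22),
    TraitSpec("PUFA", "g/dL milk", 0.140, 0.021, 1.45),
    TraitSpec("UFA", "g/dL milk", 1.190, 0.064, 1.25),
    TraitSpec("SCFA", "g/dL milk", 0.385, 0.025, 0.88),
    TraitSpec("MCFA", "g/dL milk", 2.100, 0.104, 0.88),
    TraitSpec("LCFA", "g/dL milk", 1.550, 0.110, 1.30),
    TraitSpec("branched_FA", "g/dL milk", 0.080, 0.013, 1.25),
    TraitSpec("omega3", "g/dL milk", 0.018, 0.006, 2.50),
    TraitSpec("omega6", "g/dL milk", 0.080, 0.014, 0.95),
    TraitSpec("odd_FA", "g/dL milk", 0.095, 0.016, 1.25),
    TraitSpec("trans_FA", "g/dL milk", 0.125, 0.029, 1.60),
    TraitSpec("lactoferrin", "mg/L milk", 250.0, 139.01, 1.10),
    TraitSpec("casein_alpha_s1", "g/L milk", 12.0, 0.58, 1.04),
    TraitSpec("casein_alpha_s2_K", "g/L milk", 7.5, 0.36, 1.04),
    TraitSpec("casein_beta", "g/L milk", 11.0, 1.13, 1.05),
    TraitSpec("lactalbumin", "g/L milk", 1.20, 0.15, 1.02),
    TraitSpec("lactoglobulin", "g/L milk", 3.30, 0.25, 1.05),
    TraitSpec("casein_total", "g/L milk", 27.0, 1.56, 1.05),
    TraitSpec("Na", "mg/kg milk", 400.0, 50.98, 1.00),
    TraitSpec("Ca", "mg/kg milk", 1150.0, 53.38, 1.06),
    TraitSpec("P", "mg/kg milk", 950.0, 58.71, 0.94),
    TraitSpec("K", "mg/kg milk", 1500.0, 88.14, 1.03),
    TraitSpec("Mg", "mg/kg milk", 110.0, 6.53, 1.00),
)


@dataclass
class TraitSchema:
    """Ordered collection of the 48 predictor traits."""

    traits: tuple[TraitSpec, ...] = field(default_factory=lambda: _DEFAULT_TRAITS)

    def __post_init__(self) -> None:
        if len(self.traits) == 0:
            raise ConfigurationError("trait schema is empty")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate trait names in schema")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    def __len__(self) -> int:
        return len(self.traits)

    def __getitem__(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def with_null_effects(self) -> "TraitSchema":
        """Copy of the schema with every grass multiplier set to 1.

        Under this null configuration, trait distributions carry no feeding
        signal at all: summer and winter records are exchangeable.
        """
        return TraitSchema(
            traits=tuple(
                TraitSpec(t.name, t.unit, t.baseline_mean, t.noise_sd, 1.0)
                for t in self.traits
            )
        )


def default_schema() -> TraitSchema:
    """The default 48-trait schema."""
    schema = TraitSchema()
    assert len(schema) == N_PREDICTORS
    return schema


@dataclass(frozen=True)
class FarmArchetype:
    """Feeding-management archetype of one simulated farm.

    * ``intensive`` — high-concentrate ration, little grazing
      (low peak grass fraction).
    * ``extensive`` — grass-centred management: near-full summer grazing and
      a winter ration itself richer in long-chain fatty acids
      (``winter_lcfa_offset``, g/dL added to the long-chain traits).
    * ``intermediate`` — in between.
    * ``skimmed`` — the farm submits skimmed milk for analysis: fat is
      stripped to almost nothing year-round, so its records are
      uninterpretable for feeding and must be flagged downstream.
    """

    farm_id: str
    archetype: str
    grass_amplitude: float
    winter_lcfa_offset: float = 0.0
    skimmed_flag: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.grass_amplitude <= 1.0:
            raise ConfigurationError("grass_amplitude must lie in [0, 1]")
        if self.archetype not in {"intensive", "extensive", "intermediate", "skimmed"}:
            raise ConfigurationError(f"unknown archetype {self.archetype!r}")


#: default peak grass fraction and winter LCFA offset per archetype
ARCHETYPE_DEFAULTS: dict[str, dict[str, float | bool]] = {
    "intensive": {"grass_amplitude": 0.35, "winter_lcfa_offset": 0.0, "skimmed_flag": False},
    "intermediate": {"grass_amplitude": 0.65, "winter_lcfa_offset": 0.0, "skimmed_flag": False},
    "extensive": {"grass_amplitude": 0.95, "winter_lcfa_offset": 0.12, "skimmed_flag": False},
    "skimmed": {"grass_amplitude": 0.65, "winter_lcfa_offset": 0.0, "skimmed_flag": True},
}


def make_archetype(farm_id: str, archetype: str) -> FarmArchetype:
    """Build a :class:`FarmArchetype` with the default parameters of its kind."""
    try:
        params = ARCHETYPE_DEFAULTS[archetype]
    except KeyError:
        raise ConfigurationError(f"unknown archetype {archetype!r}") from None
    return FarmArchetype(farm_id=farm_id, archetype=archetype, **params)  # type: ignore[arg-type]
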