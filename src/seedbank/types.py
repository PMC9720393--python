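"""Domain types for soil weed seed-bank surveys.

The observational unit is the quadrat: a 1 m² plot from which eighteen
soil cores (plow layer, 15 cm) are pooled, divided into parts, and the
seeds in a subset of parts counted after elutriation.  Each counted part
corresponds to a fixed ground area (0.016 m² by default), so seed counts
convert to densities via ``count / (parts_examined * part_area_m2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GUILDS = ("grass", "sedge", "broadleaf")
MODES = ("RG", "RM", "RC", "RD")
REGIONS = ("north", "middle", "south")

#: ground area (m²) represented by one counted soil part
DEFAULT_PART_AREA_M2 = 0.016
#: number of counted (elutriated) parts per quadrat
DEFAULT_PARTS_EXAMINED = 3


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One weed species with its functional-guild label.

    ``guild`` is one of grass, sedge, broadleaf.  ``rice_associated``
    flags species ecologically bound to paddy cultivation; the packaged
    occurrence table does not identify them individually, so the fixture
    leaves this False.
    """

    species_id: str
    latin_name: str
    guild: str
    rice_associated: bool = False

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValidationError(
                f"unknown guild {self.guild!r} for {self.species_id};"
                f" expected one of {GUILDS}"
            )
        if not self.species_id:
            raise ValidationError("species_id must be non-empty")


@dataclass
class QuadratCounts:
    """Seed counts of one quadrat, keyed by species id.

    Counts are numbers of seeds recovered from the counted soil parts,
    i.e. raw integers before any area conversion.
    """

    site_id: str
    mode: str
    field_id: int
    quadrat_id: int
    counts: dict[str, int] = field(default_factory=dict)
    parts_examined: int = DEFAULT_PARTS_EXAMINED
    part_area_m2: float = DEFAULT_PART_AREA_M2

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown production mode {self.mode!r}")
        if self.parts_examined < 1:
            raise ValidationError("parts_examined must be >= 1")
        if not self.part_area_m2 > 0:
            raise ValidationError("part_area_m2 must be positive")
        for sp, n in self.counts.items():
            if int(n) != n or n < 0:
                raise ValidationError(
                    f"count for {sp} in quadrat "
                    f"({self.site_id},{self.field_id},{self.quadrat_id}) "
                    f"must be a non-negative integer, got {n!r}"
                )
            self.counts[sp] = int(n)

    @property
    def sampled_area_m2(self) -> float:
        """Ground area represented by this quadrat's counted parts."""
        return self.parts_examined * self.part_area_m2

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.site_id, self.field_id, self.quadrat_id)


@dataclass(frozen=True)
class PracticeRecord:
    """Farming-practice covariates of one sampling site.

    Units: irrigation 10³ m³·ha⁻¹·yr⁻¹; organic fertilizer and green
    manure 10³ kg·ha⁻¹·yr⁻¹; crayfish kg·ha⁻¹·yr⁻¹; ducklings
    head·ha⁻¹·yr⁻¹; hand weeding h·ha⁻¹·yr⁻¹.
    """

    site_id: str
    mode: str
    consecutive_years: int
    rice_variety: str
    tillage_per_year: int
    irrigation_1e3m3_ha: float
    organic_fertilizer_1e3kg_ha: float
    green_manure_1e3kg_ha: float
    crayfish_kg_ha: float
    duckling_per_ha: float
    hand_weeding_h_ha: float
    region: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown production mode {self.mode!r}")
        if self.consecutive_years < 1:
            raise ValidationError("consecutive_years must be >= 1")
        for name in (
            "tillage_per_year",
            "irrigation_1e3m3_ha",
            "organic_fertilizer_1e3kg_ha",
            "green_manure_1e3kg_ha",
            "crayfish_kg_ha",
            "duckling_per_ha",
            "hand_weeding_h_ha",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


#: numeric practice covariates in tabulated column order
PRACTICE_NUMERIC_COLUMNS = (
    "tillage_per_year",
    "irrigation_1e3m3_ha",
    "organic_fertilizer_1e3kg_ha",
    "green_manure_1e3kg_ha",
    "crayfish_kg_ha",
    "duckling_per_ha",
    "hand_weeding_h_ha",
)
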