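"""Phytosociological parameters and importance values.

For a stratum (a set of quadrats — typically one production mode or one
field) and each species observed in it:

* absolute frequency   AF = quadrats containing the species / total quadrats
* relative frequency   RF = AF / Σ AF
* absolute density     AD = total seeds of the species / total sampled area
* relative density     RD = AD / Σ AD
* absolute abundance   AA = total seeds / quadrats containing the species
* relative abundance   RA = AA / Σ AA
* importance value     IV = RF + RD + RA

RF, RD and RA each sum to 1 over the species of the stratum, so IV sums
to 3 and ranges in [0, 3].
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import counts_matrix
from .types import QuadratCounts, SpeciesRecord, ValidationError


def counts_to_density(q: QuadratCounts) -> dict[str, float]:
    """Per-species seed density (seeds·m⁻²) of one quadrat.

    density = count / (parts_examined × part_area_m2); at the default
    geometry (3 counted parts of 0.016 m²) the divisor is 0.048 m².
    """
    area = q.sampled_area_m2
    if not area > 0:
        raise ValidationError("sampled area must be positive")
    return {sp: n / area for sp, n in q.counts.items()}


def phytosociology_table(
    quadrats: Sequence[QuadratCounts], stratum: str = ""
) -> pd.DataFrame:
    """All seven phytosociological parameters for one stratum.

    Returns a DataFrame indexed by species_id with columns AF, RF, AD,
    RD, AA, RA, IV and a ``stratum`` label column.  Species absent from
    every quadrat of the stratum are excluded.  Raises for an empty or
    all-zero stratum (the relative parameters are undefined).
    """
    if len(quadrats) == 0:
        raise ValidationError("stratum contains no quadrats")
    wide = counts_matrix(quadrats)
    present = wide.loc[:, (wide > 0).any(axis=0)]
    if present.shape[1] == 0:
        raise ValidationError(
            f"stratum {stratum!r} has no non-zero counts; relative parameters undefined"
        )
    n_quadrats = len(quadrats)
    total_area = sum(q.sampled_area_m2 for q in quadrats)

    occupancy = (present > 0).sum(axis=0)  # quadrats containing each species
    totals = present.sum(axis=0)

    af = occupancy / n_quadrats
    ad = totals / total_area
    aa = totals / occupancy

    rf = af / af.sum()
    rd = ad / ad.sum()
    ra = aa / aa.sum()

    table = pd.DataFrame(
        {
            "AF": af,
            "RF": rf,
            "AD": ad,
            "RD": rd,
            "AA": aa,
            "RA": ra,
            "IV": rf + rd + ra,
        }
    ).sort_index()
    table.index.name = "species_id"
    table["stratum"] = stratum
    return table


def guild_composition(
    table: pd.DataFrame, pool: Sequence[SpeciesRecord] | Mapping[str, str]
) -> pd.Series:
    """Percentage of total importance value held by each guild.

    ``pool`` maps species ids to guilds (either a mapping or a sequence
    of :class:`SpeciesRecord`).  Returns a Series indexed by guild
    (grass, sedge, broadleaf) summing to 100.
    """
    if not isinstance(pool, Mapping):
        pool = {s.species_id: s.guild for s in pool}
    missing = [sp for sp in table.index if sp not in pool]
    if missing:
        raise ValidationError(f"species without guild label: {missing}")
    guilds = table.index.map(pool.__getitem__)
    by_guild = table["IV"].groupby(guilds).sum()
    by_guild = by_guild.reindex(["grass", "sedge", "broadleaf"], fill_value=0.0)
    by_guild.index.name = "guild"
    return 100.0 * by_guild / table["IV"].sum()


def rank_dominants(table: pd.DataFrame, k: int = 10) -> list[str]:
    """The k species with highest IV, ties broken by species_id.

    Deterministic: sorted by descending IV, then lexicographically
    ascending species id.  If k exceeds the species count, all species
    are returned.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    order = sorted(table.index, key=lambda sp: (-table.at[sp, "IV"], sp))
    return order[: min(k, len(order))]


def stratum_tables(
    quadrats: Sequence[QuadratCounts], by: str = "mode"
) -> dict[str, pd.DataFrame]:
    """Phytosociology tables grouped by mode or by field.

    ``by='mode'`` pools all quadrats of a production mode (the
    mode-level community summary); ``by='field'`` computes one table per
    (site, field), the input to ordination.
    """
    groups: dict[str, list[QuadratCounts]] = {}
    for q in quadrats:
        if by == "mode":
            key = q.mode
        elif by == "field":
            key = f"{q.site_id}/{q.field_id}"
        else:
            raise ValidationError(f"unknown stratification {by!r}")
        groups.setdefault(key, []).append(q)
    return {key: phytosociology_table(qs, stratum=key) for key, qs in sorted(groups.items())}
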