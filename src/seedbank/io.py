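"""CSV readers and writers for surveys, practices and species tables.

The on-disk survey format is long: one row per (site, mode, field,
quadrat, species) with an integer seed count.  Species absent from a
quadrat simply have no row (equivalently count 0).  All files are UTF-8,
comma-separated, with "." as decimal mark.
"""

from __future__ import annotations

import os
from dataclasses import asdict
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    DEFAULT_PART_AREA_M2,
    DEFAULT_PARTS_EXAMINED,
    MODES,
    PracticeRecord,
    QuadratCounts,
    SpeciesRecord,
    ValidationError,
)

SURVEY_COLUMNS = ["site", "mode", "field", "quadrat", "species", "count"]


def survey_frame(quadrats: Sequence[QuadratCounts]) -> pd.DataFrame:
    """Long-format DataFrame view of a collection of quadrats.

    Rows are sorted by (site, field, quadrat, species) so that the frame
    is a canonical representation: two surveys with the same counts
    produce identical frames.
    """
    rows = []
    for q in quadrats:
        for sp in sorted(q.counts):
            rows.append((q.site_id, q.mode, q.field_id, q.quadrat_id, sp, q.counts[sp]))
    df = pd.DataFrame(rows, columns=SURVEY_COLUMNS)
    return df.sort_values(SURVEY_COLUMNS[:5], kind="stable").reset_index(drop=True)


def counts_matrix(quadrats: Sequence[QuadratCounts]) -> pd.DataFrame:
    """Quadrat × species integer count matrix (absent species = 0).

    The index is a MultiIndex (site, mode, field, quadrat); columns are
    species ids sorted lexicographically.
    """
    df = survey_frame(quadrats)
    wide = (
        df.pivot_table(
            index=["site", "mode", "field", "quadrat"],
            columns="species",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .astype(int)
        .sort_index(axis=1)
    )
    return wide


def read_survey(
    path: str | os.PathLike,
    parts_examined: int = DEFAULT_PARTS_EXAMINED,
    part_area_m2: float = DEFAULT_PART_AREA_M2,
) -> list[QuadratCounts]:
    """Read a long-format survey CSV into validated quadrat records.

    Raises :class:`ValidationError` naming the offending line for
    malformed rows, unknown modes or negative counts.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing survey columns {missing}")

    quadrats: dict[tuple, QuadratCounts] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            site = str(row.site)
            mode = str(row.mode)
            fid = int(row.field)
            qid = int(row.quadrat)
            sp = str(row.species)
            count = int(row.count)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: malformed row at line {i}: {exc}") from None
        if mode not in MODES:
            raise ValidationError(f"{path}: unknown mode {mode!r} at line {i}")
        if count < 0:
            raise ValidationError(f"{path}: negative count at line {i}")
        key = (site, fid, qid)
        q = quadrats.get(key)
        if q is None:
            q = QuadratCounts(
                site_id=site,
                mode=mode,
                field_id=fid,
                quadrat_id=qid,
                parts_examined=parts_examined,
                part_area_m2=part_area_m2,
            )
            quadrats[key] = q
        elif q.mode != mode:
            raise ValidationError(
                f"{path}: quadrat {key} appears with modes {q.mode} and {mode}"
            )
        q.counts[sp] = q.counts.get(sp, 0) + count
    return [quadrats[k] for k in sorted(quadrats)]


def write_survey(quadrats: Sequence[QuadratCounts], path: str | os.PathLike) -> None:
    """Write quadrats as a long-format survey CSV (zero counts dropped)."""
    df = survey_frame(quadrats)
    df = df[df["count"] > 0]
    df.to_csv(path, index=False)


def read_practices(path: str | os.PathLike) -> list[PracticeRecord]:
    """Read a site-level farming-practice table."""
    df = pd.read_csv(path)
    records = []
    for row in df.to_dict("records"):
        records.append(
            PracticeRecord(
                site_id=str(row["site"]),
                mode=str(row["mode"]),
                region=str(row.get("region", "") or ""),
                consecutive_years=int(row["consecutive_years"]),
                rice_variety=str(row["rice_variety"]),
                tillage_per_year=int(row["tillage_per_year"]),
                irrigation_1e3m3_ha=float(row["irrigation_1e3m3_ha"]),
                organic_fertilizer_1e3kg_ha=float(row["organic_fertilizer_1e3kg_ha"]),
                green_manure_1e3kg_ha=float(row["green_manure_1e3kg_ha"]),
                crayfish_kg_ha=float(row["crayfish_kg_ha"]),
                duckling_per_ha=float(row["duckling_per_ha"]),
                hand_weeding_h_ha=float(row["hand_weeding_h_ha"]),
            )
        )
    seen = set()
    for r in records:
        if r.site_id in seen:
            raise ValidationError(f"{path}: duplicate site {r.site_id}")
        seen.add(r.site_id)
    return records


def practices_frame(practices: Iterable[PracticeRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(p) for p in practices])
    front = ["site_id", "mode", "region", "consecutive_years", "rice_variety"]
    return df[front + [c for c in df.columns if c not in front]]


def write_practices(practices: Sequence[PracticeRecord], path: str | os.PathLike) -> None:
    df = practices_frame(practices).rename(columns={"site_id": "site"})
    df.to_csv(path, index=False)


def read_species(path: str | os.PathLike) -> list[SpeciesRecord]:
    """Read a species-attribute table (species_id, latin_name, guild, ...)."""
    df = pd.read_csv(path)
    return [
        SpeciesRecord(
            species_id=str(row["species_id"]),
            latin_name=str(row.get("latin_name", row["species_id"])),
            guild=str(row["guild"]),
            rice_associated=bool(row.get("rice_associated", False)),
        )
        for row in df.to_dict("records")
    ]


def write_species(pool: Sequence[SpeciesRecord], path: str | os.PathLike) -> None:
    pd.DataFrame([asdict(s) for s in pool]).to_csv(path, index=False)
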