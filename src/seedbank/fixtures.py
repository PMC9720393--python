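"""Packaged reference tables from the 2020 Jiangsu organic-rice survey.

Two fixtures ship with the package:

* the farming-practice table of the 12 sampling sites (one site per
  production mode × region), and
* the occurrence table of the 61 weed species recovered from the seed
  bank, with functional-guild labels and, per production mode, the
  number of sampling fields (0–3) in which each species was found.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .io import read_practices, read_species
from .types import PracticeRecord, SpeciesRecord


def _data_path(name: str):
    return importlib.resources.files("seedbank.data") / name


def load_practices_fixture() -> list[PracticeRecord]:
    """The 12 site-level practice records (one per mode × region)."""
    return read_practices(_data_path("practices_survey2020.csv"))


def load_occurrence_fixture() -> tuple[pd.DataFrame, list[SpeciesRecord]]:
    """Occurrence classes and the species pool.

    Returns a (matrix, pool) pair: ``matrix`` is a species × mode
    DataFrame of integers 0–3 (number of sampling fields per mode in
    which the species occurred; 0 = absent), indexed by species_id;
    ``pool`` is the list of :class:`SpeciesRecord`.
    """
    path = _data_path("species_occurrence2020.csv")
    df = pd.read_csv(path)
    matrix = df.set_index("species_id")[["RG", "RM", "RC", "RD"]].astype(int)
    pool = read_species(path)
    return matrix, pool
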