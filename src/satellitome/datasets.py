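"""Packaged reference tables for the Astyanax satellitome analysis.

Three small TSVs transcribed from the published A. paranae satellitome
study ship with the package:

* ``apa_satellitome.tsv`` — the 45-family catalogue (RUL, A+T, variant
  counts, per-genome Kimura divergence and abundance, printed log2).
* ``apa_a_patterns.tsv`` — A-chromosome FISH pattern (c/nc/t, "-" =
  no signal scored) of 36 satellites in A. paranae, A. fasciatus and
  A. bockmanni.
* ``b_locations.tsv`` — per-satellite cluster locations on the three B
  chromosomes (BpM, BfMa, BbM) with arm/region codes.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .cytostats import LocationRecord, read_location_table

_DATA = files("satellitome") / "data"


def load_satellitome_catalog() -> pd.DataFrame:
    """The 45-family A. paranae satellitome catalogue."""
    df = pd.read_csv(str(_DATA / "apa_satellitome.tsv"), sep="\t")
    df["superfamily"] = df["superfamily"].astype("Int64")
    return df


def load_a_patterns() -> pd.DataFrame:
    """A-chromosome FISH patterns per satellite and species."""
    return pd.read_csv(str(_DATA / "apa_a_patterns.tsv"), sep="\t")


def load_b_locations() -> list[LocationRecord]:
    """B-chromosome location records for BpM, BfMa and BbM."""
    return read_location_table(str(_DATA / "b_locations.tsv"))


def load_b_locations_frame() -> pd.DataFrame:
    return pd.read_csv(str(_DATA / "b_locations.tsv"), sep="\t")


def a_pattern_records(species: str = "A. paranae") -> list[LocationRecord]:
    """A-chromosome patterns of one species as location records."""
    df = load_a_patterns()
    if species not in df.columns:
        raise KeyError(species)
    records = []
    for _, row in df.iterrows():
        pattern = row[species]
        if pattern == "-" or pd.isna(pattern):
            continue
        records.append(
            LocationRecord(
                satellite=row["satellite"],
                species=species,
                chromosome="A",
                pattern=pattern,
            )
        )
    return records
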