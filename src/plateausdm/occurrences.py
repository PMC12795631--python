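"""Species occurrence records: CSV I/O and the in-memory container."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Tuple

import pandas as pd

from ._util import log_stage

SPECIES = ("bear", "marmot", "pika")


class OccurrenceError(ValueError):
    """Raised for malformed occurrence files."""


@dataclass
class OccurrenceSet:
    """Presence coordinates for one species.

    ``points`` are (x, y) map coordinates; ``source`` records provenance
    (field / literature / synthetic).
    """

    species: str
    points: List[Tuple[float, float]]
    source: str = "synthetic"

    def __len__(self) -> int:
        return len(self.points)


def read_occurrences(path: str | os.PathLike, species: str | None = None) -> OccurrenceSet:
    """Read a delimited occurrence table with columns species, longitude, latitude.

    Rows with unparsable coordinates are dropped and counted in the log;
    exact duplicate points are retained (spatial thinning handles them).
    """
    path = os.fspath(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise OccurrenceError(f"{path}: empty occurrence file") from None
    required = {"species", "longitude", "latitude"}
    missing = required - set(df.columns)
    if missing:
        raise OccurrenceError(f"{path}: missing required column(s) {sorted(missing)}")
    if df.empty:
        raise OccurrenceError(f"{path}: no occurrence rows")
    if species is not None:
        df = df[df["species"] == species]
    else:
        uniq = df["species"].unique()
        if len(uniq) > 1:
            raise OccurrenceError(
                f"{path}: multiple species {sorted(uniq)}; pass species= to select one")
        species = str(uniq[0])
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    ok = lon.notna() & lat.notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        log_stage("read_occurrences", path=path, species=species, dropped_unparsable=n_dropped)
    points = list(zip(lon[ok].astype(float), lat[ok].astype(float)))
    return OccurrenceSet(species=species, points=points, source="file")


def write_occurrences(occ: OccurrenceSet, path: str | os.PathLike) -> None:
    df = pd.DataFrame(occ.points, columns=["longitude", "latitude"])
    df.insert(0, "species", occ.species)
    df.to_csv(path, index=False, float_format="%.10g")
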