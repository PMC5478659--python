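"""Reading and writing the delimited formats used by the toolkit.

The central input is a long-format transect table: one row per (transect,
species) pair with the transect's centre coordinates, the species'
abundance in that transect and its dispersal class.  Coordinates are
planar metres by default; latitude/longitude input is projected with a
small-region equirectangular projection on ingest (adequate for the
km-scale extents of island sampling designs).
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

from .accumulation import REQUIRED_COLUMNS, TransectTable

__all__ = [
    "read_transect_table",
    "write_transect_table",
    "load_island_summary",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0


def _project_equirectangular(lat: pd.Series, lon: pd.Series):
    """Project lat/lon (degrees) to planar metres about the mean latitude."""
    lat0 = np.deg2rad(lat.mean())
    x = EARTH_RADIUS_M * np.cos(lat0) * np.deg2rad(lon)
    y = EARTH_RADIUS_M * np.deg2rad(lat)
    return x, y


def read_transect_table(
    path,
    delimiter: str = ",",
    latlon: bool = False,
) -> TransectTable:
    """Read and validate a transect table from delimited text.

    A header row with the columns ``transect_id, site, x, y, species_id,
    abundance, dispersal_class`` is required (``y``/``x`` are interpreted
    as latitude/longitude in degrees when ``latlon`` and projected to
    planar metres).  Duplicate (transect, species) rows are summed with a
    logged notice; nonpositive abundances, unparsable coordinates and
    species with inconsistent dispersal classes are rejected with row
    numbers.
    """
    df = pd.read_csv(path, sep=delimiter, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if latlon:
        df["x"], df["y"] = _project_equirectangular(
            pd.to_numeric(df["y"], errors="coerce"),
            pd.to_numeric(df["x"], errors="coerce"),
        )
    dups = df.duplicated(subset=["transect_id", "species_id"], keep=False)
    if dups.any():
        logger.info(
            "%s: %d duplicated (transect, species) rows summed on ingest",
            path,
            int(dups.sum()),
        )
    return TransectTable(df)


def write_transect_table(table: TransectTable, path, delimiter: str = ",") -> None:
    """Serialize a transect table as delimited text (lossless round trip)."""
    table.data.to_csv(path, sep=delimiter, index=False)


def load_island_summary() -> pd.DataFrame:
    """Published per-island summary of Azorean arthropod transect sampling.

    One row per island: number of 150 m x 5 m transects and the number of
    individuals and species per dispersal-ability class.  Used as an
    aggregation fixture; archipelago-wide species counts are not column
    sums (species are shared between islands) and are not included.
    """
    with resources.files("sadscale.data").joinpath(
        "azores_island_summary.csv"
    ).open() as fh:
        return pd.read_csv(fh)
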