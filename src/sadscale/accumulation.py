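"""Spatially ordered accumulation of transects and skewness trajectories.

Transects are standardized sampling units with planar centre coordinates.
Pooling them in order of spatial proximity treats the growing transect
count as a surrogate for growing area and sampling effort.  Two orderings
are supported:

* ``concentric`` — from a start transect, add the nearest, then the second
  nearest to the *start*, and so on;
* ``sequential`` — greedy nearest-neighbour chaining: add the transect
  nearest to the most recently added one.

Every transect serves once as the start, so a table of T transects yields
exactly T orderings per method.  The skewness of the pooled SAD at each
accumulation step, averaged over the T orderings, is the core descriptor
of how distribution shape changes with sample size; high- and low-dispersal
species are pooled separately because their SADs are predicted to change
shape at different paces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .sad import AbundanceVector, DegenerateDistributionError, skewness

__all__ = [
    "TransectTable",
    "AccumulationTrajectory",
    "order_concentric",
    "order_sequential",
    "accumulate_sads",
    "skewness_trajectory",
    "perturb_dispersal_labels",
]

REQUIRED_COLUMNS = (
    "transect_id",
    "site",
    "x",
    "y",
    "species_id",
    "abundance",
    "dispersal_class",
)

DISPERSAL_CLASSES = ("high", "low")


@dataclass
class TransectTable:
    """Validated long-format table of (transect, species) abundance records.

    One row per (transect, species) pair; duplicates are summed on
    construction.  Each species carries exactly one dispersal class
    (``high`` or ``low``) across the whole table.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        if len(df) == 0:
            raise ValueError("transect table is empty")
        abund = pd.to_numeric(df["abundance"], errors="coerce")
        bad = df.index[abund.isna() | (abund < 1) | (abund % 1 != 0)]
        if len(bad):
            raise ValueError(
                f"abundances must be positive integers; offending rows {bad.tolist()}"
            )
        df["abundance"] = abund.astype(np.int64)
        for c in ("x", "y"):
            coord = pd.to_numeric(df[c], errors="coerce")
            bad = df.index[coord.isna()]
            if len(bad):
                raise ValueError(f"unparsable {c} coordinate in rows {bad.tolist()}")
            df[c] = coord.astype(float)
        bad_cls = df.index[~df["dispersal_class"].isin(DISPERSAL_CLASSES)]
        if len(bad_cls):
            raise ValueError(
                f"dispersal_class must be one of {DISPERSAL_CLASSES}; "
                f"offending rows {bad_cls.tolist()}"
            )
        n_cls = df.groupby("species_id")["dispersal_class"].nunique()
        inconsistent = n_cls.index[n_cls > 1].tolist()
        if inconsistent:
            raise ValueError(
                f"species with inconsistent dispersal class: {inconsistent}"
            )
        # a transect must have a single centre
        for c in ("x", "y"):
            n_xy = df.groupby("transect_id")[c].nunique()
            bad_t = n_xy.index[n_xy > 1].tolist()
            if bad_t:
                raise ValueError(f"transects with conflicting coordinates: {bad_t}")
        # sum duplicated (transect, species) records
        df = (
            df.groupby(
                ["transect_id", "site", "x", "y", "species_id", "dispersal_class"],
                as_index=False,
                sort=False,
            )["abundance"]
            .sum()
            .loc[:, list(REQUIRED_COLUMNS)]
        )
        self.data = df.reset_index(drop=True)

    @property
    def transect_ids(self) -> list:
        """Transect identifiers in ascending order."""
        return sorted(self.data["transect_id"].unique().tolist())

    @property
    def species_ids(self) -> list:
        return sorted(self.data["species_id"].unique().tolist())

    @property
    def n_transects(self) -> int:
        return len(self.transect_ids)

    def coordinates(self) -> pd.DataFrame:
        """Centre coordinates per transect, indexed by transect id."""
        return (
            self.data.groupby("transect_id")[["x", "y"]].first().sort_index()
        )

    def dispersal_of(self) -> pd.Series:
        """Dispersal class per species id."""
        return self.data.groupby("species_id")["dispersal_class"].first()

    def abundance_matrix(self, group: str | None = None) -> pd.DataFrame:
        """Transect x species abundance matrix (zeros for absences).

        ``group`` restricts to one dispersal class; ``None`` keeps all
        species.
        """
        df = self.data
        if group is not None:
            if group not in DISPERSAL_CLASSES:
                raise ValueError(f"unknown dispersal group {group!r}")
            df = df[df["dispersal_class"] == group]
        mat = df.pivot_table(
            index="transect_id",
            columns="species_id",
            values="abundance",
            aggfunc="sum",
            fill_value=0,
        )
        return mat.reindex(self.transect_ids, fill_value=0)

    def pooled_abundances(self, group: str | None = None) -> AbundanceVector:
        """Pooled per-species abundances over all transects."""
        df = self.data
        if group is not None:
            df = df[df["dispersal_class"] == group]
        totals = df.groupby("species_id")["abundance"].sum()
        return AbundanceVector(totals.to_numpy())


@dataclass
class AccumulationTrajectory:
    """Pooled abundance vectors at every accumulation step, per group."""

    method: str
    start: object
    ordering: list
    vectors: dict  # group -> list of AbundanceVector, one per step t = 1..T


def _distances_from(coords: pd.DataFrame, start) -> pd.Series:
    if start not in coords.index:
        raise KeyError(f"unknown start transect {start!r}")
    d = cdist(coords.loc[[start], ["x", "y"]], coords[["x", "y"]])[0]
    return pd.Series(d, index=coords.index)


def order_concentric(table: TransectTable, start) -> list:
    """Transects sorted by Euclidean distance from the start transect.

    Ties break by ascending transect id; the start transect is first.
    """
    coords = table.coordinates()
    d = _distances_from(coords, start)
    order = sorted(coords.index, key=lambda t: (d[t], t != start, t))
    return order


def order_sequential(table: TransectTable, start) -> list:
    """Greedy nearest-neighbour chain over the remaining transects."""
    coords = table.coordinates()
    if start not in coords.index:
        raise KeyError(f"unknown start transect {start!r}")
    remaining = set(coords.index)
    order = [start]
    remaining.discard(start)
    current = start
    while remaining:
        d = _distances_from(coords, current)
        nxt = min(remaining, key=lambda t: (d[t], t))
        order.append(nxt)
        remaining.discard(nxt)
        current = nxt
    return order


_ORDERINGS = {"concentric": order_concentric, "sequential": order_sequential}


def accumulate_sads(
    table: TransectTable,
    ordering,
    groups=DISPERSAL_CLASSES,
) -> AccumulationTrajectory:
    """Pool species abundances over the first t transects, for t = 1..T.

    ``ordering`` must be a permutation of the table's transect ids.  Species
    are pooled separately per dispersal group (and for the pseudo-group
    ``"all"`` if requested).
    """
    ordering = list(ordering)
    if sorted(ordering) != table.transect_ids:
        raise ValueError("ordering is not a permutation of the transect ids")
    vectors: dict = {}
    for g in groups:
        mat = table.abundance_matrix(None if g == "all" else g)
        cum = np.cumsum(mat.loc[ordering].to_numpy(), axis=0)
        vectors[g] = [AbundanceVector(row[row > 0]) for row in cum]
    return AccumulationTrajectory("custom", ordering[0], ordering, vectors)


def skewness_trajectory(
    table: TransectTable,
    method: str = "concentric",
    groups=DISPERSAL_CLASSES,
) -> pd.DataFrame:
    """Mean and SD of SAD skewness vs number of pooled transects.

    For each of the T possible start transects the chosen ordering is
    generated and the skewness of the pooled SAD computed at every step;
    the table reports, per group and step, the mean and the sample standard
    deviation over the orderings (the +/- 2 SD band is the confidence
    interval used in plots), along with how many orderings contributed and
    how many were excluded because the pooled SAD was degenerate (fewer
    than two distinct log2 abundances).
    """
    if table.n_transects < 2:
        raise ValueError("need at least 2 transects for a trajectory")
    try:
        order_fn = _ORDERINGS[method]
    except KeyError:
        raise ValueError(f"unknown ordering method {method!r}") from None
    ids = table.transect_ids
    mats = {g: table.abundance_matrix(None if g == "all" else g) for g in groups}
    skews: dict = {g: [[] for _ in ids] for g in groups}
    excluded = {g: np.zeros(len(ids), dtype=int) for g in groups}
    for start in ids:
        ordering = order_fn(table, start)
        for g in groups:
            cum = np.cumsum(mats[g].loc[ordering].to_numpy(), axis=0)
            for t_idx, row in enumerate(cum):
                a = row[row > 0]
                try:
                    skews[g][t_idx].append(skewness(a))
                except (DegenerateDistributionError, ValueError):
                    excluded[g][t_idx] += 1
    rows = []
    for g in groups:
        for t_idx in range(len(ids)):
            vals = np.asarray(skews[g][t_idx])
            rows.append(
                {
                    "group": g,
                    "n_transects": t_idx + 1,
                    "mean_skewness": vals.mean() if vals.size else np.nan,
                    "sd_skewness": (
                        vals.std(ddof=1) if vals.size > 1 else np.nan
                    ),
                    "n_orderings": int(vals.size),
                    "n_excluded": int(excluded[g][t_idx]),
                }
            )
    return pd.DataFrame(rows)


def perturb_dispersal_labels(
    table: TransectTable, fraction: float, seed: int
) -> TransectTable:
    """Flip the dispersal class of a random fraction of species.

    Emulates misidentification of dispersal ability: ``round(fraction * S)``
    species are chosen uniformly without replacement (deterministically for
    a given seed) and their class swapped high <-> low in every record.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    species = table.species_ids
    n_flip = int(round(fraction * len(species)))
    rng = np.random.default_rng(seed)
    flip = set(rng.choice(len(species), size=n_flip, replace=False).tolist())
    flip_ids = {species[i] for i in flip}
    df = table.data.copy()
    mask = df["species_id"].isin(flip_ids)
    swap = {"high": "low", "low": "high"}
    df.loc[mask, "dispersal_class"] = df.loc[mask, "dispersal_class"].map(swap)
    return TransectTable(df)
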