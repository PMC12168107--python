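"""Occurrence cleaning, filtering and rasterization into a presence matrix.

The pipeline is: coordinate cleaning (suspicious coordinates, land, exact
duplicates) -> temporal window -> species retention rules -> aggregation of
records onto the grid, with multiple records of a species in one cell
collapsing to a single presence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .grid import GridSpec, wrap_lon

__all__ = [
    "CleanReport",
    "PresenceMatrix",
    "clean_coordinates",
    "filter_temporal",
    "select_species",
    "rasterize",
]

REQUIRED_COLUMNS = ["species", "decimalLongitude", "decimalLatitude", "year", "month"]


@dataclass
class CleanReport:
    """Per-rule removal counts; removed + retained equals the input count."""

    n_input: int = 0
    equal_lon_lat: int = 0
    zero_zero: int = 0
    on_land: int = 0
    out_of_extent: int = 0
    duplicates: int = 0
    out_of_window: int = 0
    missing_date: int = 0
    retained: int = 0

    @property
    def removed(self) -> int:
        return (
            self.equal_lon_lat + self.zero_zero + self.on_land + self.out_of_extent
            + self.duplicates + self.out_of_window + self.missing_date
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, getattr(self, k)) for k in (
            "n_input", "equal_lon_lat", "zero_zero", "on_land", "out_of_extent",
            "duplicates", "out_of_window", "missing_date", "retained",
        )]
        return pd.DataFrame(rows, columns=["rule", "count"])


def clean_coordinates(
    records: pd.DataFrame,
    grid: GridSpec,
    land_mask: np.ndarray | None = None,
    report: CleanReport | None = None,
) -> tuple[pd.DataFrame, CleanReport]:
    """Remove records with suspicious or unusable coordinates.

    Rules, applied in order so each record is counted under one rule:
    equal longitude and latitude; the (0, 0) point; outside the grid extent;
    on a land cell of ``land_mask`` (True = ocean); exact duplicate rows.
    """
    rep = report if report is not None else CleanReport(n_input=len(records))
    if report is None:
        rep.n_input = len(records)
    df = records.copy()
    # the equal-coordinates rule applies to the values as reported, before
    # any longitude wrapping
    raw_lon = df["decimalLongitude"].to_numpy(dtype=float)
    bad_eq = raw_lon == df["decimalLatitude"].to_numpy(dtype=float)
    df["decimalLongitude"] = wrap_lon(raw_lon)

    lon = df["decimalLongitude"].to_numpy(dtype=float)
    lat = df["decimalLatitude"].to_numpy(dtype=float)
    bad_zero = (lon == 0) & (lat == 0)
    bad_eq = bad_eq & ~bad_zero  # null island counts under its own rule
    cell = np.asarray(grid.cell_of(lon, lat))
    bad_extent = cell < 0
    if land_mask is not None:
        bad_land = np.zeros(len(df), dtype=bool)
        inside = ~bad_extent
        bad_land[inside] = ~np.asarray(land_mask, dtype=bool)[cell[inside]]
    else:
        bad_land = np.zeros(len(df), dtype=bool)

    rep.equal_lon_lat += int(bad_eq.sum())
    rep.zero_zero += int(bad_zero.sum())
    rep.out_of_extent += int((bad_extent & ~bad_eq & ~bad_zero).sum())
    rep.on_land += int((bad_land & ~bad_extent & ~bad_eq & ~bad_zero).sum())
    keep = ~(bad_eq | bad_zero | bad_extent | bad_land)
    df = df.loc[keep]

    dup = df.duplicated(subset=REQUIRED_COLUMNS, keep="first")
    rep.duplicates += int(dup.sum())
    df = df.loc[~dup].reset_index(drop=True)
    rep.retained = len(df)
    return df, rep


def filter_temporal(
    records: pd.DataFrame,
    years: tuple[int, int] = (1950, 2019),
    months: set[int] = frozenset({10, 11, 12, 1, 2, 3}),
    report: CleanReport | None = None,
) -> tuple[pd.DataFrame, CleanReport]:
    """Keep records inside the survey year window and the austral
    spring/summer months; records missing a date are removed and counted
    separately."""
    rep = report if report is not None else CleanReport(n_input=len(records))
    yr = pd.to_numeric(records["year"], errors="coerce")
    mo = pd.to_numeric(records["month"], errors="coerce")
    missing = yr.isna() | mo.isna()
    ok = (~missing) & yr.between(years[0], years[1]) & mo.isin(list(months))
    rep.missing_date += int(missing.sum())
    rep.out_of_window += int((~ok & ~missing).sum())
    out = records.loc[ok].reset_index(drop=True)
    rep.retained = len(out)
    return out, rep


def select_species(
    records: pd.DataFrame,
    grid: GridSpec,
    study_area_lat_max: float = -30.0,
    min_occ: int = 10,
    endemic_frac: float = 0.5,
) -> pd.DataFrame:
    """Apply the two retention rules on cell-aggregated presences.

    A species is retained iff it has at least ``min_occ`` presence cells
    inside the study area (latitude <= ``study_area_lat_max``), OR more than
    ``endemic_frac`` of its total presence cells fall inside it (rescuing
    rare endemics the first rule would drop). Records anywhere on the globe
    are aggregated at the grid's resolution for both counts.

    Returns a per-species summary (n_in_area, n_total, in_frac, retained).
    """
    lon = records["decimalLongitude"].to_numpy(dtype=float)
    lat = records["decimalLatitude"].to_numpy(dtype=float)
    res = grid.resolution
    gcol = np.floor(wrap_lon(lon) / res).astype(np.int64)
    grow = np.floor(lat / res).astype(np.int64)
    df = pd.DataFrame(
        {
            "species": records["species"].to_numpy(),
            "gcell": grow * 400_000 + gcol,  # unique global cell key
            "in_area": lat <= study_area_lat_max,
        }
    ).drop_duplicates(subset=["species", "gcell"])
    agg = df.groupby("species")["in_area"].agg(n_in_area="sum", n_total="count")
    agg["in_frac"] = agg["n_in_area"] / agg["n_total"]
    agg["retained"] = (agg["n_in_area"] >= min_occ) | (agg["in_frac"] > endemic_frac)
    return agg.reset_index()


def _dedupe_presences(records: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    cell = np.asarray(
        grid.cell_of(
            records["decimalLongitude"].to_numpy(dtype=float),
            records["decimalLatitude"].to_numpy(dtype=float),
        )
    )
    df = pd.DataFrame({"species": records["species"].to_numpy(), "cell": cell})
    return df.loc[df["cell"] >= 0].drop_duplicates()


@dataclass
class PresenceMatrix:
    """Binary species x grid-cell incidence.

    ``cells`` lists the occupied cell ids (columns); ``matrix`` is sparse
    boolean with one row per species. ``global_counts`` keeps each species'
    pre-filter worldwide presence-cell count for the endemism bookkeeping.
    """

    species: list[str]
    cells: np.ndarray
    matrix: sparse.csr_matrix
    global_counts: pd.Series | None = None
    grid: GridSpec | None = None

    @property
    def n_presences(self) -> int:
        return int(self.matrix.nnz)

    def species_richness(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def range_size(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def to_triplets(self) -> pd.DataFrame:
        coo = self.matrix.tocoo()
        return pd.DataFrame(
            {
                "species": [self.species[i] for i in coo.row],
                "cell_id": self.cells[coo.col],
                "presence": 1,
            }
        )


def rasterize(
    records: pd.DataFrame,
    grid: GridSpec,
    species_subset: list[str] | None = None,
    global_counts: pd.Series | None = None,
) -> PresenceMatrix:
    """Aggregate cleaned records onto the grid: incidence is 1 iff the
    species has at least one record in the cell. Cells with no presences are
    dropped from the matrix columns."""
    pres = _dedupe_presences(records, grid)
    if species_subset is not None:
        pres = pres.loc[pres["species"].isin(set(species_subset))]
    if pres.empty:
        raise ValueError("no presences to rasterize")
    species = sorted(pres["species"].unique())
    cells = np.sort(pres["cell"].unique())
    srow = pd.Categorical(pres["species"], categories=species).codes
    ccol = np.searchsorted(cells, pres["cell"].to_numpy())
    mat = sparse.csr_matrix(
        (np.ones(len(pres), dtype=np.int8), (srow, ccol)),
        shape=(len(species), len(cells)),
    )
    mat.data[:] = 1
    return PresenceMatrix(species, cells, mat, global_counts=global_counts, grid=grid)
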