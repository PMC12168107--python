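"""Regular lon/lat grid used throughout the pipeline.

Cells are half-open ``[edge, edge + resolution)`` intervals on both axes and
are enumerated row-major starting at ``(lat_min, lon_min)``, i.e. cell 0 is
the south-western corner and ids increase eastward first, then northward.
Longitudes are wrapped into ``[-180, 180)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "make_grid", "wrap_lon"]


def wrap_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class GridSpec:
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = 1.0
    n_lon: int = field(init=False)
    n_lat: int = field(init=False)

    def __post_init__(self):
        for span, name in (
            (self.lon_max - self.lon_min, "lon"),
            (self.lat_max - self.lat_min, "lat"),
        ):
            n = span / self.resolution
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} extent is not a multiple of resolution")
            if round(n) < 2:
                raise ValueError(f"{name} extent must span at least 2 cells")
        object.__setattr__(self, "n_lon", int(round((self.lon_max - self.lon_min) / self.resolution)))
        object.__setattr__(self, "n_lat", int(round((self.lat_max - self.lat_min) / self.resolution)))

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    # --- coordinate <-> cell id mapping -------------------------------------

    def cell_of(self, lon, lat):
        """Map coordinates to cell ids; -1 for points outside the extent.

        Interior edges belong to the cell whose lower edge they are
        (half-open convention); the top/right outer edges are outside.
        """
        lon = wrap_lon(lon)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(np.int64)
        row = np.floor((lat - self.lat_min) / self.resolution).astype(np.int64)
        inside = (col >= 0) & (col < self.n_lon) & (row >= 0) & (row < self.n_lat)
        out = np.where(inside, row * self.n_lon + col, -1)
        return out if out.ndim else int(out)

    def cell_centers(self):
        """(lon, lat) arrays of cell centers, index = cell id."""
        lons = self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution
        lats = self.lat_min + (np.arange(self.n_lat) + 0.5) * self.resolution
        glon, glat = np.meshgrid(lons, lats)  # rows = lat, row-major flatten
        return wrap_lon(glon.ravel()), glat.ravel()

    def cell_lat_bounds(self):
        """(lat_bottom, lat_top) per cell id, degrees."""
        rows = np.arange(self.n_cells) // self.n_lon
        bottom = self.lat_min + rows * self.resolution
        return bottom, bottom + self.resolution


def make_grid(
    lon_min: float = -180.0,
    lon_max: float = 180.0,
    lat_min: float = -75.0,
    lat_max: float = -30.0,
    resolution: float = 1.0,
) -> GridSpec:
    """Build a regular grid; extents must be whole multiples of ``resolution``."""
    return GridSpec(lon_min, lon_max, lat_min, lat_max, resolution)
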