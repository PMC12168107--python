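"""Readers and writers for the pipeline's interchange formats.

Occurrences travel as CSV (species, decimalLongitude, decimalLatitude, year,
month); environmental fields as long CSV (lon, lat, depth, variable, value)
or NetCDF; presence matrices as sparse triplet CSV. Writers that emit
generated data record the seed and parameters in a JSON sidecar next to the
file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec
from .occurrences import PresenceMatrix
from .synthetic import EnvField

__all__ = [
    "write_occurrences",
    "read_occurrences",
    "write_env_long",
    "read_env_long",
    "write_field_netcdf",
    "write_presence_triplets",
    "read_presence_triplets",
    "write_partition",
    "write_sidecar",
]


def write_sidecar(path: str | Path, metadata: dict) -> Path:
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps(metadata, indent=2, default=str))
    return side


def write_occurrences(records: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> Path:
    path = Path(path)
    records.to_csv(path, index=False)
    if metadata is not None:
        write_sidecar(path, metadata)
    return path


def read_occurrences(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_env_long(stack: dict[str, EnvField], path: str | Path, metadata: dict | None = None) -> Path:
    path = Path(path)
    frames = []
    for fld in stack.values():
        lon, lat = fld.grid.cell_centers()
        ok = fld.mask
        frames.append(
            pd.DataFrame(
                {
                    "lon": lon[ok],
                    "lat": lat[ok],
                    "depth": fld.depth,
                    "variable": fld.variable,
                    "value": fld.values[ok],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if metadata is not None:
        write_sidecar(path, metadata)
    return path


def read_env_long(path: str | Path, grid: GridSpec) -> dict[str, EnvField]:
    df = pd.read_csv(path)
    stack: dict[str, EnvField] = {}
    for (variable, depth), sub in df.groupby(["variable", "depth"]):
        values = np.full(grid.n_cells, np.nan)
        cells = np.asarray(grid.cell_of(sub["lon"].to_numpy(), sub["lat"].to_numpy()))
        values[cells] = sub["value"].to_numpy()
        mask = np.isfinite(values)
        stack[f"{variable}_{int(depth)}"] = EnvField(variable, float(depth), values, mask, grid)
    return stack


def write_field_netcdf(fld: EnvField, path: str | Path) -> Path:
    """NetCDF3 export via the SciPy backend (dims lat, lon)."""
    import xarray as xr

    grid = fld.grid
    lons = grid.lon_min + (np.arange(grid.n_lon) + 0.5) * grid.resolution
    lats = grid.lat_min + (np.arange(grid.n_lat) + 0.5) * grid.resolution
    da = xr.DataArray(
        fld.values.reshape(grid.n_lat, grid.n_lon),
        coords={"lat": lats, "lon": lons},
        dims=("lat", "lon"),
        name=fld.variable,
        attrs={"depth_m": fld.depth},
    )
    da.to_netcdf(path, engine="scipy")
    return Path(path)


def write_presence_triplets(pm: PresenceMatrix, path: str | Path) -> Path:
    path = Path(path)
    pm.to_triplets().to_csv(path, index=False)
    return path


def read_presence_triplets(path: str | Path, grid: GridSpec | None = None) -> PresenceMatrix:
    from scipy import sparse

    df = pd.read_csv(path)
    species = sorted(df["species"].unique())
    cells = np.sort(df["cell_id"].unique())
    rows = pd.Categorical(df["species"], categories=species).codes
    cols = np.searchsorted(cells, df["cell_id"].to_numpy())
    mat = sparse.csr_matrix(
        (np.ones(len(df), dtype=np.int8), (rows, cols)), shape=(len(species), len(cells))
    )
    mat.data[:] = 1
    return PresenceMatrix(species, cells, mat, grid=grid)


def write_partition(net, partition, assignment, path: str | Path) -> Path:
    """Node table: id, kind, module, region (0 = unassigned)."""
    path = Path(path)
    region = np.array(
        [assignment.module_to_region.get(int(m), 0) for m in partition.modules]
    )
    pd.DataFrame(
        {
            "node_id": net.node_names(),
            "node_type": net.node_kinds(),
            "module": partition.modules,
            "region": region,
        }
    ).to_csv(path, index=False)
    return path
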