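"""Readers/writers for the pipeline's on-disk formats.

Gridded series and fields travel as NetCDF (xarray, scipy backend),
tables as CSV, dendrogram records as JSON and configuration as YAML.
Cell ordering is canonical 0-based row-major throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .characteristics import GriddedFireSeries
from .grid import GridSpec


def fire_series_to_dataset(series: GriddedFireSeries) -> xr.Dataset:
    coords = {"cell": np.arange(series.n_cells),
              "year": np.asarray(series.years),
              "month": np.arange(1, 13)}
    dims = ("cell", "year", "month")
    return xr.Dataset(
        {
            "burned_area": (dims, series.burned_area),
            "fire_count": (dims, series.fire_count.astype("int32")),
            "mean_fire_size": (dims, series.mean_fire_size),
        },
        coords=coords,
        attrs={"cell_area_km2": series.cell_area},
    )


def write_fire_series(series: GriddedFireSeries, path: str | Path) -> None:
    fire_series_to_dataset(series).to_netcdf(path, engine="scipy")


def read_fire_series(path: str | Path) -> GriddedFireSeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        return GriddedFireSeries(
            burned_area=ds["burned_area"].values.copy(),
            fire_count=ds["fire_count"].values.copy(),
            mean_fire_size=ds["mean_fire_size"].values.copy(),
            years=[int(y) for y in ds["year"].values],
            cell_area=float(ds.attrs["cell_area_km2"]),
        )


def read_gridded(path: str | Path, variable: str) -> np.ndarray:
    """Read one variable from a NetCDF file in canonical cell order."""
    path = Path(path)
    if path.suffix not in {".nc", ".cdf", ".netcdf"}:
        raise ValueError(f"unknown format {path.suffix!r}; expected NetCDF")
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise KeyError(f"variable {variable!r} not in {path.name}: {list(ds)}")
        return ds[variable].values.copy()


def write_field(values: np.ndarray, path: str | Path, name: str,
                grid: GridSpec | None = None) -> None:
    """Write a per-cell field (1-D) or per-cell series (2-D) as NetCDF."""
    arr = np.asarray(values)
    dims = ("cell",) if arr.ndim == 1 else ("cell", "time")
    ds = xr.Dataset({name: (dims, arr)})
    if grid is not None:
        ds.attrs.update(n_rows=grid.n_rows, n_cols=grid.n_cols,
                        cell_area_km2=grid.cell_area)
    ds.to_netcdf(path, engine="scipy")


def write_labels_csv(labels: np.ndarray, path: str | Path,
                     extra: dict[str, np.ndarray] | None = None) -> None:
    df = pd.DataFrame({"cell_id": np.arange(len(labels)), "label": labels})
    for k, v in (extra or {}).items():
        df[k] = v
    df.to_csv(path, index=False)


def write_dendrogram_json(Z: np.ndarray, path: str | Path) -> None:
    record = {"linkage": np.asarray(Z).tolist(),
              "columns": ["left", "right", "height", "size"]}
    Path(path).write_text(json.dumps(record))


def read_dendrogram_json(path: str | Path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text())["linkage"])


def save_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
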