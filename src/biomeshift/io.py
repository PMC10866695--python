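"""Raster, vector and climate-cube readers/writers.

Single-band rasters travel as ESRI ASCII grids (plain text, readable by any
GIS), monthly climate cubes as NetCDF (via xarray), road networks as GeoJSON
LineStrings. Every reader returns the layer together with its
:class:`~biomeshift.grids.GridDescriptor` and every writer refuses grids that
do not match the data shape, so a run can never silently mix georeferences.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grids import GridDescriptor, GridMismatchError, check_same_grid

__all__ = [
    "write_raster",
    "read_raster",
    "write_climate_cube",
    "read_climate_cube",
    "write_roads_geojson",
    "read_roads_geojson",
    "regrid_nearest",
]

_NODATA = -9999.0


def write_raster(path: str | Path, values: np.ndarray, grid: GridDescriptor) -> Path:
    """Write a single-band raster as an ESRI ASCII grid.

    NaN values are stored as the NODATA sentinel and come back as NaN.
    Values round-trip bit-identically (17 significant digits).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise GridMismatchError(
            f"data shape {values.shape} does not match grid {grid.shape}"
        )
    path = Path(path)
    out = np.where(np.isfinite(values), values, _NODATA)
    header = (
        f"ncols {grid.cols}\n"
        f"nrows {grid.rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {(grid.origin_lat - grid.rows * grid.pixel_size)!r}\n"
        f"cellsize {grid.pixel_size!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, GridDescriptor]:
    """Read an ESRI ASCII grid; NODATA cells come back as NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (rows, cols):
        raise ValueError(f"raster body {values.shape} disagrees with header ({rows}, {cols})")
    grid = GridDescriptor(
        rows=rows,
        cols=cols,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + rows * header["cellsize"],
        pixel_size=header["cellsize"],
    )
    nodata = header.get("nodata_value", _NODATA)
    values = np.where(values == nodata, np.nan, values)
    return values, grid


def write_climate_cube(path: str | Path, cube, name: str = "values") -> Path:
    """Write a MonthlyClimateCube to NetCDF (CF-style year/month/lat/lon axes)."""
    import xarray as xr

    g = cube.grid
    da = xr.DataArray(
        cube.values,
        dims=("year", "month", "lat", "lon"),
        coords={
            "year": np.asarray(cube.years, dtype=np.int32),
            "month": np.arange(1, 13, dtype=np.int32),
            "lat": g.lats(),
            "lon": g.lons(),
        },
        name=name,
    )
    da.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")
    return Path(path)


def read_climate_cube(path: str | Path, name: str = "values"):
    """Read a NetCDF file written by :func:`write_climate_cube`."""
    import xarray as xr

    from .climate import MonthlyClimateCube

    with xr.open_dataset(path, engine="scipy") as ds:
        da = ds[name].load()
    lats = da["lat"].values
    lons = da["lon"].values
    ps = float(abs(lats[0] - lats[1])) if lats.size > 1 else float(abs(lons[1] - lons[0]))
    grid = GridDescriptor(
        rows=lats.size,
        cols=lons.size,
        origin_lon=float(lons[0]) - ps / 2,
        origin_lat=float(lats[0]) + ps / 2,
        pixel_size=ps,
    )
    return MonthlyClimateCube(
        values=da.values, years=da["year"].values.astype(int), grid=grid
    )


def write_roads_geojson(path: str | Path, roads) -> Path:
    """Write road polylines (shapely LineStrings) as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"road_id": i},
            "geometry": {"type": "LineString", "coordinates": [list(c) for c in r.coords]},
        }
        for i, r in enumerate(roads)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return Path(path)


def read_roads_geojson(path: str | Path):
    from shapely.geometry import LineString

    with open(path) as fh:
        fc = json.load(fh)
    return [LineString(f["geometry"]["coordinates"]) for f in fc["features"]]


def regrid_nearest(values: np.ndarray, src: GridDescriptor, dst: GridDescriptor) -> np.ndarray:
    """Nearest-neighbour regrid from ``src`` onto ``dst``.

    A blunt instrument, provided because multi-resolution sources must be
    harmonised before analysis; cells of ``dst`` outside ``src`` become NaN.
    """
    import warnings

    warnings.warn(
        "nearest-neighbour regridding; harmonise grids upstream where possible",
        stacklevel=2,
    )
    lon, lat = dst.centers()
    idx = src.cell_index(lon.ravel(), lat.ravel())
    flat = np.asarray(values, dtype=float).ravel()
    out = np.full(idx.shape, np.nan)
    ok = idx >= 0
    out[ok] = flat[idx[ok]]
    return out.reshape(dst.shape)
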