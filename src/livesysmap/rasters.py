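"""Raster container and plain-text grid I/O.

All spatial layers are square-celled, unprojected lat/long (WGS 84) grids.
The on-disk format is the ESRI ASCII grid (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
rows of whitespace-separated values, north row first.  Values round-trip
at float32 precision or better; the geotransform round-trips exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RasterGrid",
    "RasterBundle",
    "read_ascii_grid",
    "write_ascii_grid",
    "pixel_area_km2",
]

#: default nodata sentinel used on export
DEFAULT_NODATA = -1.0

#: 5 arc minutes in decimal degrees
FIVE_ARCMIN = 0.083333


@dataclass
class RasterGrid:
    """A single-band grid of non-negative values with a geotransform.

    Parameters
    ----------
    values
        2-D float array, row 0 = northernmost row.
    xllcorner, yllcorner
        Lower-left corner of the grid in decimal degrees.
    cellsize
        Square pixel size in decimal degrees.
    nodata
        Sentinel marking invalid pixels.
    """

    values: np.ndarray
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = FIVE_ARCMIN
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if not (self.cellsize > 0):
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid(self) -> np.ndarray:
        """Boolean grid of pixels that carry data."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with nodata/non-finite pixels replaced by ``fill``."""
        out = self.values.copy()
        out[~self.valid()] = fill
        return out

    def like(self, values: np.ndarray) -> "RasterGrid":
        """A new grid with the same geotransform carrying ``values``."""
        if values.shape != self.shape:
            raise ValueError(f"shape mismatch: {values.shape} vs {self.shape}")
        return replace(self, values=np.asarray(values, dtype=float))

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.xllcorner, other.xllcorner, abs_tol=1e-9)
            and math.isclose(self.yllcorner, other.yllcorner, abs_tol=1e-9)
            and math.isclose(self.cellsize, other.cellsize, rel_tol=1e-12)
        )


def require_coregistered(*grids: RasterGrid) -> None:
    """Raise if the grids do not share shape and geotransform."""
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_grid(g):
            raise ValueError(
                f"rasters are not co-registered: {ref.shape}@"
                f"({ref.xllcorner},{ref.yllcorner},{ref.cellsize}) vs "
                f"{g.shape}@({g.xllcorner},{g.yllcorner},{g.cellsize})"
            )


@dataclass
class RasterBundle:
    """The co-registered input layers for one species run.

    ``unit_map`` assigns each pixel to an admin unit (integer id ≥ 1;
    0 = outside any unit) and is the authority for unit membership.
    """

    livestock: RasterGrid
    population: RasterGrid
    urban: np.ndarray
    elevation: RasterGrid
    slope: RasterGrid
    snow_ice: np.ndarray
    unit_map: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), int))

    def __post_init__(self) -> None:
        self.urban = np.asarray(self.urban, dtype=bool)
        self.snow_ice = np.asarray(self.snow_ice, dtype=bool)
        self.unit_map = np.asarray(self.unit_map, dtype=int)
        require_coregistered(self.livestock, self.population, self.elevation, self.slope)
        for name in ("urban", "snow_ice", "unit_map"):
            arr = getattr(self, name)
            if arr.shape != self.livestock.shape:
                raise ValueError(f"{name} shape {arr.shape} != {self.livestock.shape}")

    def unit_ids(self) -> np.ndarray:
        ids = np.unique(self.unit_map)
        return ids[ids > 0]


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster."""
    path = Path(path)
    nrows, ncols = grid.shape
    header = (
        f"ncols         {ncols}\n"
        f"nrows         {nrows}\n"
        f"xllcorner     {grid.xllcorner!r}\n"
        f"yllcorner     {grid.yllcorner!r}\n"
        f"cellsize      {grid.cellsize!r}\n"
        f"NODATA_value  {grid.nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%.9g")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid` (or GDAL)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: body shape {values.shape} != header ({nrows},{ncols})")
    return RasterGrid(
        values=values,
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 1.0),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )


def pixel_area_km2(grid: RasterGrid) -> np.ndarray:
    """Per-pixel area in km² on the sphere, varying with latitude.

    Used only when exporting head-per-km² densities; the allocation
    itself works in head per pixel.
    """
    nrows, _ = grid.shape
    r_earth = 6371.0
    # latitude of each row centre, north row first
    lat_top = grid.yllcorner + nrows * grid.cellsize
    lats = lat_top - (np.arange(nrows) + 0.5) * grid.cellsize
    dlat = np.deg2rad(grid.cellsize)
    cell_h = r_earth * dlat
    cell_w = r_earth * dlat * np.cos(np.deg2rad(lats))
    area_row = cell_h * cell_w
    return np.repeat(area_row[:, None], grid.shape[1], axis=1)
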