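"""Geographic temperature rasters: I/O, point extraction, and distances.

A :class:`RasterGrid` is a regular latitude/longitude grid (geographic WGS84,
no projection) holding maximum-summer-temperature (Tmax) values in the
WorldClim v1.4 storage dialect: **tenths of a degree Celsius**.  Conversion to
degrees Celsius happens in exactly one place (:attr:`RasterGrid.values_c` /
:func:`value_at`), so that every consumer downstream works in plain degrees C.

Grids are serialized as ESRI ASCII grids, a plain-text format readable by any
GIS.  Points are assigned to cells by a half-open rule (see :func:`cell_index`)
so that boundary points belong to exactly one cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: IUGG mean Earth radius, km.  Pinned so distances are bit-reproducible.
EARTH_RADIUS_KM = 6371.0088

#: km per degree of arc on a great circle of that sphere.
KM_PER_DEGREE = 2.0 * math.pi * EARTH_RADIUS_KM / 360.0


class RasterError(ValueError):
    """Raised for malformed raster files or out-of-contract raster queries."""


class OutOfExtentError(RasterError):
    """A queried point lies outside the grid extent."""


@dataclass
class RasterGrid:
    """Regular geographic grid of Tmax values stored in tenths of degrees C.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Cell values in tenths of degrees C; ``nodata`` marks missing cells.
        Row 0 is the northernmost row (image convention).
    lat_nw, lon_nw : float
        Latitude/longitude of the grid's north-west **corner** (not the first
        cell center).
    cell_size : float
        Cell edge length in decimal degrees; cells are square.
    nodata : float
        Sentinel value for missing cells.
    """

    values: np.ndarray
    lat_nw: float
    lon_nw: float
    cell_size: float
    nodata: float = -9999.0
    crs: str = field(default="WGS84", repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise RasterError("cell_size must be positive")
        if self.crs.upper() not in {"WGS84", "EPSG:4326", "CRS84"}:
            raise RasterError(
                f"only geographic WGS84 grids are supported, got CRS {self.crs!r}"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def lat_s(self) -> float:
        """Latitude of the southern grid edge."""
        return self.lat_nw - self.n_rows * self.cell_size

    @property
    def lon_e(self) -> float:
        """Longitude of the eastern grid edge."""
        return self.lon_nw + self.n_cols * self.cell_size

    @property
    def values_c(self) -> np.ndarray:
        """Values in degrees C with NaN at nodata cells (the single /10)."""
        out = self.values / 10.0
        out[self.values == self.nodata] = np.nan
        return out

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of the center of cell (row, col)."""
        lat = self.lat_nw - (row + 0.5) * self.cell_size
        lon = self.lon_nw + (col + 0.5) * self.cell_size
        return lat, lon

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of cell-center latitudes (n_rows,) and longitudes (n_cols,)."""
        rows = np.arange(self.n_rows)
        cols = np.arange(self.n_cols)
        lats = self.lat_nw - (rows + 0.5) * self.cell_size
        lons = self.lon_nw + (cols + 0.5) * self.cell_size
        return lats, lons


def cell_index(grid: RasterGrid, lat: float, lon: float) -> tuple[int, int]:
    """Map a WGS84 point to the (row, col) of the unique cell containing it.

    Half-open convention: ``row = floor((lat_nw - lat)/cell_size)``,
    ``col = floor((lon - lon_nw)/cell_size)``, so a point exactly on an
    interior cell boundary belongs to the higher-row (southern) / higher-col
    (eastern) cell.  Points on the southern or eastern grid edge are outside.
    """
    _validate_point(lat, lon)
    row = math.floor((grid.lat_nw - lat) / grid.cell_size)
    col = math.floor((lon - grid.lon_nw) / grid.cell_size)
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise OutOfExtentError(
            f"point ({lat}, {lon}) outside grid extent "
            f"lat [{grid.lat_s}, {grid.lat_nw}), lon [{grid.lon_nw}, {grid.lon_e})"
        )
    return row, col


def value_at(grid: RasterGrid, lat: float, lon: float) -> float:
    """Tmax in degrees C at a point, from the single containing pixel.

    No interpolation is performed: the value is that of the unique cell under
    the point, converted from stored tenths of degrees C.  Returns NaN when
    the cell is nodata; raises :class:`OutOfExtentError` outside the grid.
    """
    row, col = cell_index(grid, lat, lon)
    v = grid.values[row, col]
    if v == grid.nodata:
        return math.nan
    return v / 10.0


def in_range_mask(grid: RasterGrid, interval: tuple[float, float]) -> np.ndarray:
    """Boolean grid: cell is True iff ``t_lo <= value_c <= t_hi`` and not nodata."""
    t_lo, t_hi = interval
    vc = grid.values_c
    with np.errstate(invalid="ignore"):
        return (vc >= t_lo) & (vc <= t_hi)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a sphere of radius 6371.0088 km.

    Accepts scalars or numpy arrays (broadcasting as usual).
    """
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def distance_to_range(
    grid: RasterGrid, interval: tuple[float, float], lat: float, lon: float
) -> float:
    """Distance (km) from a point to the nearest cell with in-range Tmax.

    Zero when the point's own cell is in range; otherwise the minimum
    great-circle distance from the point to the **center** of any in-range
    cell.  Raises :class:`RasterError` when no cell is in range.
    """
    mask = in_range_mask(grid, interval)
    if not mask.any():
        raise RasterError(
            f"no raster cell has Tmax within [{interval[0]}, {interval[1]}] degrees C"
        )
    try:
        row, col = cell_index(grid, lat, lon)
        if mask[row, col]:
            return 0.0
    except OutOfExtentError:
        pass  # off-grid points still get a distance to the nearest in-range cell
    lats, lons = grid.cell_centers()
    rr, cc = np.nonzero(mask)
    d = haversine_km(lat, lon, lats[rr], lons[cc])
    return float(d.min())


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_raster(path) -> RasterGrid:
    """Read a single-band ESRI ASCII grid (geographic coordinates, WGS84).

    The six-line header (``ncols .. NODATA_value``) is followed by rows of
    whitespace-separated values, northernmost row first.  Values are taken to
    be in tenths of degrees C (the WorldClim v1.4 dialect).
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise RasterError(f"{path}: truncated header")
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise RasterError(f"{path}: missing header keys {missing}")
        body = np.loadtxt(fh, dtype=float, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (n_rows, n_cols):
        raise RasterError(
            f"{path}: body shape {body.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    lat_nw = header["yllcorner"] + n_rows * cell
    grid = RasterGrid(
        values=body,
        lat_nw=lat_nw,
        lon_nw=header["xllcorner"],
        cell_size=cell,
        nodata=nodata,
    )
    if not (-90.0 <= grid.lat_s and grid.lat_nw <= 90.0):
        raise RasterError(f"{path}: grid latitudes outside [-90, 90] — not WGS84?")
    return grid


def write_raster(grid: RasterGrid, path) -> None:
    """Write a grid as an ESRI ASCII grid; lossless round-trip with read_raster."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(grid.lon_nw)!r}\n")
        fh.write(f"yllcorner {float(grid.lat_s)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def _validate_point(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValueError(f"({lat}, {lon}) is not a valid WGS84 coordinate")
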