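"""Shared geospatial primitives: grids, rasters, occurrence points, distances, I/O.

All coordinates are WGS84 decimal degrees (longitude, latitude). Distances are
great-circle kilometres on a sphere of radius 6371.0088 km; no projection step
is ever applied, so kilometre thresholds (1 km thinning, 20 km buffers) are
exact at any latitude.

Rasters are lon/lat-gridded with cell-center registration and row 0 at the
north edge. On-disk format is the ESRI ASCII grid (``.asc``), a plain-text
raster interchange format; points travel as headered CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

PROTOCOLS = ("stationary", "traveling", "area", "specimen", "unknown")


class SpatialError(ValueError):
    """Base class for coordinate / grid / parse errors."""


class CoordinateError(SpatialError):
    pass


class ExtentError(SpatialError):
    pass


class ParseError(SpatialError):
    pass


# ---------------------------------------------------------------------------
# Grid and raster types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: edges, cell size, and shape.

    Cell centers sit at ``edge + (index + 0.5) * cell_size``; row 0 is the
    northernmost row, column 0 the westernmost column.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise SpatialError("grid extent must have lon_min < lon_max and lat_min < lat_max")
        if self.cell_size <= 0:
            raise SpatialError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise SpatialError("grid must contain at least one cell per axis")

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        # row 0 = north
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.lon_min + (col + 0.5) * self.cell_size,
            self.lat_max - (row + 0.5) * self.cell_size,
        )

    def cell_index(self, lon, lat):
        """Map point(s) to (row, col) of the containing cell.

        Points on a cell boundary belong to the cell whose center is nearest;
        exact midpoints go to the higher column (east) and the lower row index
        (north). Points outside the extent raise :class:`ExtentError`.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        eps = 1e-12
        out = (
            (lon < self.lon_min - eps)
            | (lon > self.lon_max + eps)
            | (lat < self.lat_min - eps)
            | (lat > self.lat_max + eps)
        )
        if np.any(out):
            bad = np.argwhere(np.atleast_1d(out))[0]
            raise ExtentError(f"point outside grid extent at flat index {bad.tolist()}")
        colf = (lon - self.lon_min) / self.cell_size
        col_round = np.round(colf)
        # exact lon boundary -> higher column (eastern cell), float-tolerant
        col = np.where(np.isclose(colf, col_round), col_round, np.floor(colf)).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        rowf = (self.lat_max - lat) / self.cell_size
        row = np.floor(rowf).astype(int)
        # exact lat boundary -> lower row index (northern cell)
        on_edge = np.isclose(rowf, np.round(rowf)) & (np.round(rowf) > 0)
        row = np.where(on_edge, np.round(rowf).astype(int) - 1, row)
        row = np.clip(row, 0, self.n_rows - 1)
        if np.ndim(lon) == 0:
            return int(row), int(col)
        return row, col


@dataclass
class RasterGrid:
    """A single named layer on a :class:`GridSpec`.

    ``values`` has shape ``spec.shape``; entries under ``nodata_mask`` are
    ignored, everywhere else they must be finite.
    """

    spec: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise SpatialError(
                f"raster shape {self.values.shape} does not match spec {self.spec.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.spec.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.spec.shape:
                raise SpatialError("nodata mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise SpatialError(f"raster {self.name!r} has non-finite values outside nodata")

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        return RasterGrid(self.spec, values, self.nodata_mask.copy(), name or self.name)


@dataclass
class EnvStack:
    """Ordered, co-registered predictor layers with unique names."""

    layers: list[RasterGrid]

    def __post_init__(self) -> None:
        if not self.layers:
            raise SpatialError("empty stack")
        spec0 = self.layers[0].spec
        for layer in self.layers:
            if layer.spec != spec0:
                raise SpatialError("stack layers must share one GridSpec")
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise SpatialError("stack layer names must be unique")

    @property
    def spec(self) -> GridSpec:
        return self.layers[0].spec

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def joint_nodata(self) -> np.ndarray:
        mask = np.zeros(self.spec.shape, dtype=bool)
        for layer in self.layers:
            mask |= layer.nodata_mask
        return mask

    def __getitem__(self, name: str) -> RasterGrid:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)

    def as_array(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) value cube."""
        return np.stack([l.values for l in self.layers])


# ---------------------------------------------------------------------------
# Occurrence points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OccurrenceRecord:
    lon: float
    lat: float
    protocol: str = "unknown"
    distance_km: float | None = None
    area_km2: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0) or not (-90.0 <= self.lat <= 90.0):
            raise CoordinateError(f"invalid coordinates ({self.lon}, {self.lat})")
        if self.protocol not in PROTOCOLS:
            raise CoordinateError(f"unknown protocol {self.protocol!r}")
        if self.distance_km is not None:
            if self.protocol != "traveling":
                raise CoordinateError("distance_km only valid for traveling counts")
            if self.distance_km < 0:
                raise CoordinateError("distance_km must be nonnegative")
        if self.area_km2 is not None:
            if self.protocol != "area":
                raise CoordinateError("area_km2 only valid for area counts")
            if self.area_km2 < 0:
                raise CoordinateError("area_km2 must be nonnegative")


@dataclass
class OccurrenceSet:
    records: list[OccurrenceRecord] = field(default_factory=list)
    species: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat)."""
        if not self.records:
            return np.empty((0, 2))
        return np.array([(r.lon, r.lat) for r in self.records])

    def subset(self, idx: Iterable[int]) -> "OccurrenceSet":
        idx = list(idx)
        return OccurrenceSet([self.records[i] for i in idx], self.species)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def haversine_km(a, b) -> np.ndarray | float:
    """Great-circle distance in km between (lon, lat) points.

    Accepts single points or broadcastable arrays of shape (..., 2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for p in (a, b):
        lon, lat = p[..., 0], p[..., 1]
        if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
            raise CoordinateError("coordinates outside lon [-180,180] / lat [-90,90]")
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    if d.ndim == 0:
        return float(d)
    return d


def pairwise_haversine_km(points: np.ndarray) -> np.ndarray:
    """Full (n, n) distance matrix for an (n, 2) lon/lat array."""
    points = np.asarray(points, dtype=float)
    return haversine_km(points[:, None, :], points[None, :, :])


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------


def extract_at_points(stack: EnvStack, points) -> tuple[np.ndarray, np.ndarray]:
    """Sample every layer at each (lon, lat) point.

    Returns ``(matrix, nodata_flags)``: one row per point, one column per
    layer, plus a boolean vector flagging points that fell in a joint-nodata
    cell. Points outside the extent raise :class:`ExtentError`.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rows, cols = stack.spec.cell_index(pts[:, 0], pts[:, 1])
    cube = stack.as_array()
    matrix = cube[:, rows, cols].T
    flags = stack.joint_nodata()[rows, cols]
    return matrix, flags


# ---------------------------------------------------------------------------
# Raster I/O — ESRI ASCII grid
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_raster(grid: RasterGrid, path) -> None:
    """Write a raster as an ESRI ASCII grid (plain text, row 0 = north)."""
    spec = grid.spec
    values = np.where(grid.nodata_mask, _NODATA, grid.values)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.lon_min!r}\n"
        f"yllcorner {spec.lat_min!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt="%.10g")


def read_raster(path, name: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_raster` (or any tool)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                if parts and parts[0].lower() == "nodata_value":
                    raise ParseError(f"{path}: malformed header line {line!r}")
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(0)
        skip = len(header)
        try:
            values = np.loadtxt(fh, skiprows=skip, ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path}: could not parse raster body: {exc}") from None
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ParseError(f"{path}: missing header field {key!r}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (n_rows, n_cols):
        raise ParseError(
            f"{path}: body shape {values.shape} does not match header ({n_rows}, {n_cols})"
        )
    cell = header["cellsize"]
    spec = GridSpec(
        lon_min=header["xllcorner"],
        lon_max=header["xllcorner"] + n_cols * cell,
        lat_min=header["yllcorner"],
        lat_max=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
    )
    nodata = header.get("nodata_value", _NODATA)
    mask = values == nodata
    values = np.where(mask, 0.0, values)
    return RasterGrid(spec, values, mask, name or path.stem)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Point I/O — headered CSV
# ---------------------------------------------------------------------------

_LON_ALIASES = ("longitude", "lon", "long", "x")
_LAT_ALIASES = ("latitude", "lat", "y")


def write_points(occ: OccurrenceSet, path) -> None:
    rows = []
    for r in occ.records:
        rows.append(
            {
                "longitude": r.lon,
                "latitude": r.lat,
                "protocol": r.protocol,
                "distance_km": r.distance_km if r.distance_km is not None else "",
                "area_km2": r.area_km2 if r.area_km2 is not None else "",
                "source_id": r.source_id,
            }
        )
    pd.DataFrame(rows, columns=["longitude", "latitude", "protocol", "distance_km", "area_km2", "source_id"]).to_csv(path, index=False)


def read_points(path, species: str = "") -> OccurrenceSet:
    """Read occurrence points from CSV; columns mapped by header name.

    Required: longitude/latitude (aliases lon/lat accepted). Optional:
    protocol, distance_km, area_km2, source_id. Invalid rows raise
    :class:`ParseError` naming the offending 1-based data row.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from None
    cols = {c.strip().lower(): c for c in df.columns}
    lon_col = next((cols[a] for a in _LON_ALIASES if a in cols), None)
    lat_col = next((cols[a] for a in _LAT_ALIASES if a in cols), None)
    if lon_col is None or lat_col is None:
        raise ParseError(f"{path}: need longitude and latitude columns, got {list(df.columns)}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            protocol = row.get(cols.get("protocol", ""), "unknown")
            if not isinstance(protocol, str) or not protocol:
                protocol = "unknown"
            records.append(
                OccurrenceRecord(
                    lon=float(row[lon_col]),
                    lat=float(row[lat_col]),
                    protocol=protocol.strip().lower(),
                    distance_km=_opt_float(row.get(cols.get("distance_km", ""))),
                    area_km2=_opt_float(row.get(cols.get("area_km2", ""))),
                    source_id=str(row.get(cols.get("source_id", ""), "") or ""),
                )
            )
        except (SpatialError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from None
    return OccurrenceSet(records, species=species)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)
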