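"""Biotic-interaction predictor: rasterize resource-plant points by buffering.

A cell scores 1 when its center lies within ``radius_km`` great-circle
kilometres of any source point (inclusive radius on cell centers), 0
otherwise; nodata cells stay nodata. The membership test is an exhaustive
nearest-point distance over all cell centers — deterministic and
resolution-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spatial import GridSpec, OccurrenceSet, RasterGrid, haversine_km


@dataclass
class BioticLayer:
    grid: RasterGrid
    radius_km: float
    source_points: OccurrenceSet


def rasterize_buffer(
    points: OccurrenceSet,
    radius_km: float = 20.0,
    spec: GridSpec | None = None,
    nodata_mask: np.ndarray | None = None,
    name: str = "biotic",
) -> BioticLayer:
    """Binary presence layer: 1 iff a cell center is <= radius_km from a point.

    Zero points yield an all-zero layer. Works in latitude bands so the
    pairwise distance matrix never materializes for the whole grid at once.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    if spec is None:
        raise ValueError("a GridSpec is required")
    n_rows, n_cols = spec.shape
    values = np.zeros((n_rows, n_cols))
    src = points.coords()
    if len(src):
        lons = spec.lon_centers()
        lats = spec.lat_centers()
        # prune by a generous bounding box around the source points
        max_abs_lat = min(89.0, max(abs(spec.lat_min), abs(spec.lat_max)))
        deg_pad = radius_km / (111.0 * max(0.05, np.cos(np.radians(max_abs_lat)))) + spec.cell_size
        lon_ok = (lons >= src[:, 0].min() - deg_pad) & (lons <= src[:, 0].max() + deg_pad)
        lat_ok = (lats >= src[:, 1].min() - deg_pad) & (lats <= src[:, 1].max() + deg_pad)
        cols = np.flatnonzero(lon_ok)
        for r in np.flatnonzero(lat_ok):
            centers = np.column_stack([lons[cols], np.full(cols.size, lats[r])])
            d = haversine_km(centers[:, None, :], src[None, :, :])
            values[r, cols] = (d.min(axis=1) <= radius_km).astype(float)
    mask = (
        np.zeros((n_rows, n_cols), dtype=bool) if nodata_mask is None else nodata_mask.copy()
    )
    values[mask] = 0.0
    grid = RasterGrid(spec, values, mask, name=name)
    return BioticLayer(grid=grid, radius_km=radius_km, source_points=points)
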