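"""Cumulative viewshed analysis over a digital surface model (DSM).

Observers stand ``eye_height`` m above the DSM surface at fixed intervals
along road polylines.  A target cell is visible from an observer when no
surface sample strictly between them rises above the straight sight line; the
count of observers seeing each cell is the cell's *viewshed points*, and a
pond's visibility score is the sum of viewshed points over the cells inside
its polygon.

Definition of the line-of-sight test (shared by the fast kernel and by
:func:`line_of_sight`):

* the surface is sampled by bilinear interpolation at arc positions
  ``los_step, 2*los_step, ...`` strictly between observer and target
  (both endpoints excluded);
* a sample blocks iff its surface elevation is *strictly* greater than the
  sight-line elevation at that position (grazing rays count as visible);
* the target elevation is the bare surface value of the target cell — no
  target-height offset;
* the 500 m range limit is a horizontal (2-D) distance to the cell center;
* the observer's own cell is always visible;
* nodata cells block nothing and are never visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .landscape_io import FeatureSet, RasterGrid, densify_polyline, rasterize_polygon
from .landscape_io import SimplePolygon


@dataclass
class VisibilityParams:
    """Tunables of the viewshed procedure.

    spacing: interval (m) between observation points along roads.
    eye_height: observer height (m) above the DSM surface.
    max_distance: sight-line range limit (m, horizontal).
    los_step: ray sampling step (m); defaults to half the DSM cell size.
    """

    spacing: float = 100.0
    eye_height: float = 1.5
    max_distance: float = 500.0
    los_step: float | None = None

    def resolve_step(self, cell_size: float) -> float:
        step = self.los_step if self.los_step is not None else cell_size / 2.0
        if step <= 0 or step > cell_size:
            raise ValueError(f"los_step must be in (0, cell_size], got {step}")
        return step

    def __post_init__(self) -> None:
        if min(self.spacing, self.eye_height, self.max_distance) <= 0:
            raise ValueError("spacing, eye_height and max_distance must be positive")


@dataclass
class ObserverPoint:
    x: float
    y: float
    eye_z: float


def bilinear_surface(dsm: RasterGrid, x: float, y: float) -> float:
    """Bilinear interpolation of the DSM at a point, clamped at the edges."""
    fc = x_to_frac_col(dsm, x)
    fr = y_to_frac_row(dsm, y)
    return _bilinear(dsm.values, fr, fc)


def x_to_frac_col(dsm: RasterGrid, x: float) -> float:
    return (x - dsm.x_origin) / dsm.cell_size - 0.5


def y_to_frac_row(dsm: RasterGrid, y: float) -> float:
    return (y - dsm.y_origin) / dsm.cell_size - 0.5


@njit(cache=True)
def _bilinear(values, fr, fc):  # pragma: no cover - exercised via wrappers
    n_rows, n_cols = values.shape
    r0 = int(math.floor(fr))
    c0 = int(math.floor(fc))
    tr = fr - r0
    tc = fc - c0
    if r0 < 0:
        r0, tr = 0, 0.0
    if c0 < 0:
        c0, tc = 0, 0.0
    if r0 >= n_rows - 1:
        r0, tr = n_rows - 1, 0.0
    if c0 >= n_cols - 1:
        c0, tc = n_cols - 1, 0.0
    r1 = min(r0 + 1, n_rows - 1)
    c1 = min(c0 + 1, n_cols - 1)
    v00 = values[r0, c0]
    v01 = values[r0, c1]
    v10 = values[r1, c0]
    v11 = values[r1, c1]
    top = v00 * (1.0 - tc) + v01 * tc
    bot = v10 * (1.0 - tc) + v11 * tc
    return top * (1.0 - tr) + bot * tr


def generate_observer_points(
    roads: FeatureSet, dsm: RasterGrid, params: VisibilityParams | None = None
) -> list[ObserverPoint]:
    """Observation points at ``params.spacing`` intervals along each road,
    ``params.eye_height`` m above the bilinear DSM surface."""
    params = params or VisibilityParams()
    observers: list[ObserverPoint] = []
    for road in roads:
        for x, y in road.vertices:
            if not dsm.contains_point(x, y):
                raise ValueError(f"road {road.id!r} leaves the DSM extent at ({x}, {y})")
        for x, y in densify_polyline(road, params.spacing):
            observers.append(
                ObserverPoint(x, y, bilinear_surface(dsm, x, y) + params.eye_height)
            )
    return observers


def line_of_sight(
    dsm: RasterGrid,
    obs: ObserverPoint,
    target_cell: tuple[int, int],
    params: VisibilityParams | None = None,
) -> bool:
    """Single-pair visibility test implementing the module's LOS definition."""
    params = params or VisibilityParams()
    step = params.resolve_step(dsm.cell_size)
    row, col = target_cell
    if not (0 <= row < dsm.n_rows and 0 <= col < dsm.n_cols):
        raise ValueError(f"target cell {target_cell} outside DSM")
    tx, ty = dsm.cell_center(row, col)
    dist = math.hypot(tx - obs.x, ty - obs.y)
    if dist > params.max_distance:
        raise ValueError(
            f"target at distance {dist:.1f} m exceeds max_distance {params.max_distance} m"
        )
    if dsm.values[row, col] == dsm.nodata:
        return False
    # observer's own cell is always visible
    orow = int((obs.y - dsm.y_origin) / dsm.cell_size)
    ocol = int((obs.x - dsm.x_origin) / dsm.cell_size)
    if (orow, ocol) == (row, col) or dist == 0.0:
        return True
    tz = dsm.values[row, col]
    nodata_fill = _nodata_filled(dsm)
    n = int(math.ceil(dist / step)) - 1  # samples at step, 2*step, ... < dist
    if n * step >= dist:
        n -= 1
    for i in range(1, n + 1):
        t = (i * step) / dist
        sx = obs.x + t * (tx - obs.x)
        sy = obs.y + t * (ty - obs.y)
        sz = _bilinear(
            nodata_fill, y_to_frac_row(dsm, sy), x_to_frac_col(dsm, sx)
        )
        line_z = obs.eye_z + t * (tz - obs.eye_z)
        if sz > line_z:
            return False
    return True


def _nodata_filled(dsm: RasterGrid) -> np.ndarray:
    """DSM values with nodata cells lowered so they can never block a ray."""
    vals = dsm.values
    mask = dsm.nodata_mask()
    if mask.any():
        vals = vals.copy()
        vals[mask] = -1e30
    return np.ascontiguousarray(vals, dtype=np.float64)


@njit(cache=True)
def _viewshed_one_observer(
    values, nodata_mask, counts, x0, y0, cs, ox, oy, oz, max_dist, step
):  # pragma: no cover - exercised via compute_viewshed_counts
    n_rows, n_cols = values.shape
    r_lo = max(0, int(math.floor((oy - max_dist - y0) / cs - 0.5)))
    r_hi = min(n_rows - 1, int(math.ceil((oy + max_dist - y0) / cs - 0.5)))
    c_lo = max(0, int(math.floor((ox - max_dist - x0) / cs - 0.5)))
    c_hi = min(n_cols - 1, int(math.ceil((ox + max_dist - x0) / cs - 0.5)))
    orow = int((oy - y0) / cs)
    ocol = int((ox - x0) / cs)
    for row in range(r_lo, r_hi + 1):
        ty = y0 + (row + 0.5) * cs
        for col in range(c_lo, c_hi + 1):
            if nodata_mask[row, col]:
                continue
            tx = x0 + (col + 0.5) * cs
            dist = math.hypot(tx - ox, ty - oy)
            if dist > max_dist:
                continue
            if (row == orow and col == ocol) or dist == 0.0:
                counts[row, col] += 1
                continue
            tz = values[row, col]
            n = int(math.ceil(dist / step)) - 1
            if n * step >= dist:
                n -= 1
            visible = True
            for i in range(1, n + 1):
                t = (i * step) / dist
                sz = _bilinear(
                    values,
                    (oy + t * (ty - oy) - y0) / cs - 0.5,
                    (ox + t * (tx - ox) - x0) / cs - 0.5,
                )
                if sz > oz + t * (tz - oz):
                    visible = False
                    break
            if visible:
                counts[row, col] += 1


def compute_viewshed_counts(
    dsm: RasterGrid,
    observers: list[ObserverPoint],
    params: VisibilityParams | None = None,
) -> RasterGrid:
    """Count, per cell, the observers whose sight line reaches the cell.

    Exact with respect to the module's LOS definition; deterministic.
    """
    params = params or VisibilityParams()
    step = params.resolve_step(dsm.cell_size)
    counts = np.zeros(dsm.values.shape, dtype=np.float64)
    values = _nodata_filled(dsm)
    nodata = np.ascontiguousarray(dsm.nodata_mask())
    for obs in observers:
        _viewshed_one_observer(
            values,
            nodata,
            counts,
            dsm.x_origin,
            dsm.y_origin,
            dsm.cell_size,
            obs.x,
            obs.y,
            obs.eye_z,
            params.max_distance,
            step,
        )
    return RasterGrid(dsm.x_origin, dsm.y_origin, dsm.cell_size, counts, nodata=-1.0)


def pond_visibility(counts: RasterGrid, pond: SimplePolygon) -> int:
    """A pond's visibility score: summed viewshed points of the cells whose
    centers fall inside the pond polygon."""
    mask = rasterize_polygon(pond, counts)
    geom = pond.to_shapely()
    xmin, ymin, xmax, ymax = geom.bounds
    if xmax < counts.x_origin or xmin > counts.x_max or ymax < counts.y_origin or ymin > counts.y_max:
        raise ValueError(f"pond {pond.id!r} lies entirely outside the count grid")
    return int(np.round(counts.values[mask].sum()))
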