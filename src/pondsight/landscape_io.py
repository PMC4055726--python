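"""Raster and vector primitives shared by every other module.

All coordinates are planar Cartesian metres in a projected grid; there is no
geographic CRS handling.  Rasters follow the ESRI ASCII grid convention on
disk but are stored row-0-south in memory, so that cell ``(r, c)`` has its
center at ``(x_origin + (c + 0.5) * cell_size, y_origin + (r + 0.5) * cell_size)``
with ``r`` increasing northward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, mapping, shape


class RasterFormatError(ValueError):
    """Raised when a raster file does not parse under the declared dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RasterGrid:
    """A planar grid of elevations, counts, or category codes.

    Parameters
    ----------
    x_origin, y_origin
        Coordinates (m) of the lower-left corner of the grid.
    cell_size
        Cell edge length in metres; cells are square.
    values
        ``(n_rows, n_cols)`` array with row 0 at the *south* edge.
    nodata
        Sentinel marking cells with no data.  Nodata cells are ignored by
        visibility and aggregation operations.
    """

    x_origin: float
    y_origin: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a 2-D array with >= 1 row and column")
        body = self.values[self.values != self.nodata]
        if body.size and not np.all(np.isfinite(body)):
            raise ValueError("non-nodata raster values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_origin + self.n_rows * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_origin + (col + 0.5) * self.cell_size,
            self.y_origin + (row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x-coordinates of all column centers, y-coordinates of all row centers."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_origin + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def contains_point(self, x: float, y: float) -> bool:
        return (
            self.x_origin <= x <= self.x_max and self.y_origin <= y <= self.y_max
        )

    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            self.x_origin, self.y_origin, self.cell_size, self.values.copy(), self.nodata
        )


@dataclass
class Polyline:
    """An ordered open chain of planar vertices (roads, rivers, canals)."""

    id: str
    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 2:
            raise ValueError(f"polyline {self.id!r} needs >= 2 vertices")
        for a, b in zip(self.vertices, self.vertices[1:]):
            if a == b:
                raise ValueError(f"polyline {self.id!r} has consecutive duplicate vertices")

    @property
    def length(self) -> float:
        v = np.asarray(self.vertices)
        return float(np.sum(np.hypot(*(v[1:] - v[:-1]).T)))

    def to_shapely(self) -> LineString:
        return LineString(self.vertices)


@dataclass
class SimplePolygon:
    """A single-ring polygon with optional holes (ponds, land-use patches)."""

    id: str
    exterior: list[tuple[float, float]]
    holes: list[list[tuple[float, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        geom = Polygon(self.exterior, self.holes)
        if not geom.is_valid:
            raise ValueError(f"polygon {self.id!r} is invalid (self-intersecting ring?)")
        if geom.area <= 0:
            raise ValueError(f"polygon {self.id!r} has zero area")

    @property
    def area(self) -> float:
        return self.to_shapely().area

    def to_shapely(self) -> Polygon:
        return Polygon(self.exterior, self.holes)

    @classmethod
    def from_shapely(cls, pid: str, geom: Polygon) -> "SimplePolygon":
        return cls(
            pid,
            list(geom.exterior.coords),
            [list(r.coords) for r in geom.interiors],
        )


@dataclass
class FeatureSet:
    """A homogeneous collection of named geometries with attributes."""

    kind: str  # roads | rivers | ponds | landuse
    features: list  # Polyline or SimplePolygon
    attributes: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate feature ids in {self.kind} set")
        kinds = {type(f) for f in self.features}
        if len(kinds) > 1:
            raise ValueError("FeatureSet geometries must be homogeneous")

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, fid: str):
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _format_value(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def read_raster(path, dialect: str = "esri_ascii") -> RasterGrid:
    """Read a raster file.

    Only the ``esri_ascii`` dialect is supported; the interface accepts a
    dialect name so other formats can be added behind it.
    """
    if dialect != "esri_ascii":
        raise NotImplementedError(f"raster dialect {dialect!r} is not supported")
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(f"malformed header value for {key!r}") from exc
            i += 1
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise RasterFormatError(f"missing or malformed header key {key!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    rows = []
    for r, line in enumerate(lines[i:]):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != n_cols:
            raise RasterFormatError(
                f"row {r} has {len(parts)} values, expected ncols={n_cols}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise RasterFormatError(f"non-numeric value in row {r}") from exc
    if len(rows) != n_rows:
        raise RasterFormatError(f"found {len(rows)} data rows, expected nrows={n_rows}")
    # file lists north first; flip to row-0-south storage
    values = np.asarray(rows, dtype=float)[::-1]
    return RasterGrid(header["xllcorner"], header["yllcorner"], header["cellsize"], values, nodata)


def write_raster(grid: RasterGrid, path, dialect: str = "esri_ascii") -> None:
    """Write a raster; round-trips bit-exactly with :func:`read_raster`."""
    if dialect != "esri_ascii":
        raise NotImplementedError(f"raster dialect {dialect!r} is not supported")
    out = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {_format_value(grid.x_origin)}",
        f"yllcorner {_format_value(grid.y_origin)}",
        f"cellsize {_format_value(grid.cell_size)}",
    ]
    if np.any(grid.nodata_mask()):
        out.append(f"NODATA_value {_format_value(grid.nodata)}")
    for row in grid.values[::-1]:
        out.append(" ".join(_format_value(v) for v in row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# vector I/O (GeoJSON)
# ---------------------------------------------------------------------------


def read_features(path, kind: str) -> FeatureSet:
    """Read a GeoJSON FeatureCollection into a :class:`FeatureSet`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    feats, attrs = [], {}
    for f in doc.get("features", []):
        geom = shape(f["geometry"])
        props = dict(f.get("properties") or {})
        fid = str(props.pop("id", f.get("id", len(feats))))
        if geom.geom_type == "LineString":
            feats.append(Polyline(fid, list(geom.coords)))
        elif geom.geom_type == "Polygon":
            feats.append(SimplePolygon.from_shapely(fid, geom))
        else:
            raise ValueError(f"unsupported geometry type {geom.geom_type}")
        attrs[fid] = props
    return FeatureSet(kind, feats, attrs)


def write_features(fs: FeatureSet, path) -> None:
    features = []
    for f in fs.features:
        geom = f.to_shapely()
        props = {"id": f.id, **fs.attributes.get(f.id, {})}
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# geometric operations
# ---------------------------------------------------------------------------


def densify_polyline(line: Polyline, spacing: float) -> list[tuple[float, float]]:
    """Points at arc lengths 0, spacing, 2*spacing, ... strictly below total length.

    The first vertex is always included; a line shorter than ``spacing``
    yields exactly one point.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    verts = np.asarray(line.vertices, dtype=float)
    seg = verts[1:] - verts[:-1]
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    points: list[tuple[float, float]] = []
    s, k = 0.0, 0
    while s < total:
        j = int(np.searchsorted(cum, s, side="right") - 1)
        j = min(j, len(seg_len) - 1)
        t = (s - cum[j]) / seg_len[j]
        p = verts[j] + t * seg[j]
        points.append((float(p[0]), float(p[1])))
        k += 1
        s = k * spacing
    return points


def rasterize_polygon(poly: SimplePolygon, template: RasterGrid) -> np.ndarray:
    """Boolean mask: True where a cell *center* lies inside (or on) the polygon."""
    geom = poly.to_shapely()
    if geom.area <= 0:
        raise ValueError("degenerate polygon")
    xs, ys = template.cell_centers()
    xmin, ymin, xmax, ymax = geom.bounds
    mask = np.zeros((template.n_rows, template.n_cols), dtype=bool)
    cols = np.nonzero((xs >= xmin - template.cell_size) & (xs <= xmax + template.cell_size))[0]
    rows = np.nonzero((ys >= ymin - template.cell_size) & (ys <= ymax + template.cell_size))[0]
    if cols.size == 0 or rows.size == 0:
        return mask
    cc, rr = np.meshgrid(cols, rows)
    # intersects == covers for points: boundary counts as inside
    hit = shapely.intersects_xy(geom, xs[cc].ravel(), ys[rr].ravel())
    mask[rr.ravel(), cc.ravel()] = hit
    return mask


def buffer_polygon(poly: SimplePolygon, distance: float, quad_segs: int = 16) -> SimplePolygon:
    """Ring buffer: the zone within ``distance`` outward of the polygon's edge,
    excluding the polygon itself.

    Arcs around convex corners are approximated with ``quad_segs`` segments per
    quadrant (chord error < distance/64 at the default).
    """
    if distance <= 0:
        raise ValueError(f"buffer distance must be > 0, got {distance}")
    geom = poly.to_shapely()
    ring = geom.buffer(distance, quad_segs=quad_segs).difference(geom)
    if ring.geom_type != "Polygon":  # pragma: no cover - simple inputs stay simple
        ring = max(ring.geoms, key=lambda g: g.area)
    return SimplePolygon.from_shapely(f"{poly.id}_buf{distance:g}", ring)


def clip_length(lines: FeatureSet, region: SimplePolygon) -> float:
    """Total length (m) of all line portions inside ``region``; empty input -> 0."""
    geom = region.to_shapely()
    total = 0.0
    for line in lines:
        total += line.to_shapely().intersection(geom).length
    return total
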