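"""Per-pond environmental characteristics and the modelling table.

Eight candidate characteristics are assembled per pond: visibility (viewshed
points), road density and urban ratio in a 500 m ring buffer, river densities
over graded ring buffers, connectivity with upstream reservoirs through the
canal network, surface area, chlorophyll-a concentration, and a winter
drainage flag.  Densities are metres of line per square metre of buffer
(m/m^2) internally; CSV export scales road and river densities by 1e3 to the
conventional 1e-3 m/m^2 display unit, stated in the column names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .landscape_io import (
    FeatureSet,
    RasterGrid,
    SimplePolygon,
    buffer_polygon,
    clip_length,
    rasterize_polygon,
)

RIVER_BUFFERS = (5, 10, 25, 50, 100, 250, 500, 1000)

#: land-use category codes used by category rasters
LANDUSE_CODES = {"woodland": 1, "farmland": 2, "urban": 3}


@dataclass
class CanalGraph:
    """Directed water-flow graph over reservoirs, canals, ponds and farmland."""

    edges: list[tuple[str, str]]
    node_kinds: dict[str, str]  # node id -> reservoir | canal | pond | farmland

    def __post_init__(self) -> None:
        valid = {"reservoir", "canal", "pond", "farmland"}
        bad = set(self.node_kinds.values()) - valid
        if bad:
            raise ValueError(f"unknown node kinds: {sorted(bad)}")
        for s, t in self.edges:
            if s not in self.node_kinds or t not in self.node_kinds:
                raise ValueError(f"edge ({s!r}, {t!r}) references unknown node")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n, k in self.node_kinds.items():
            g.add_node(n, kind=k)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_csv(cls, path) -> "CanalGraph":
        """Edge-list CSV (source,target,source_kind,target_kind); rows with an
        empty target declare isolated nodes."""
        df = pd.read_csv(path, dtype=str)
        kinds: dict[str, str] = {}
        edges = []
        for row in df.itertuples(index=False):
            kinds[row.source] = row.source_kind
            if isinstance(row.target, str) and row.target:
                kinds[row.target] = row.target_kind
                edges.append((row.source, row.target))
        return cls(edges, kinds)

    def to_csv(self, path) -> None:
        rows = [
            {
                "source": s,
                "target": t,
                "source_kind": self.node_kinds[s],
                "target_kind": self.node_kinds[t],
            }
            for s, t in self.edges
        ]
        linked = {n for e in self.edges for n in e}
        rows += [
            {"source": n, "target": "", "source_kind": k, "target_kind": ""}
            for n, k in sorted(self.node_kinds.items())
            if n not in linked
        ]
        pd.DataFrame(rows, columns=["source", "target", "source_kind", "target_kind"]).to_csv(
            path, index=False
        )


@dataclass
class PondRecord:
    """One pond's feature vector plus species presence labels."""

    pond_id: str
    visibility: int
    road_density: float  # m/m^2
    urban_ratio: float
    river_density: dict[int, float]  # buffer m -> m/m^2
    connectivity: int  # 0 none, 1 indirect, 2 direct
    area: float  # m^2
    chl_a: float  # ug/L
    drained: int
    present_bluegill: int | None = None
    present_bass: int | None = None

    def __post_init__(self) -> None:
        if self.visibility < 0 or self.road_density < 0 or self.area <= 0:
            raise ValueError(f"pond {self.pond_id}: negative density or non-positive area")
        if not 0.0 <= self.urban_ratio <= 1.0:
            raise ValueError(f"pond {self.pond_id}: urban_ratio outside [0, 1]")
        if self.connectivity not in (0, 1, 2):
            raise ValueError(f"pond {self.pond_id}: connectivity must be 0, 1 or 2")
        if self.chl_a <= 0:
            raise ValueError(f"pond {self.pond_id}: chl_a must be positive")


def trophic_class(chl_a: float) -> str:
    """OECD-style trophic category from chlorophyll-a (ug/L):
    hypertrophic >= 25, eutrophic in [8, 25), sub_eutrophic below 8."""
    if chl_a <= 0:
        raise ValueError(f"chl_a must be positive, got {chl_a}")
    if chl_a >= 25:
        return "hypertrophic"
    if chl_a >= 8:
        return "eutrophic"
    return "sub_eutrophic"


def road_density(roads: FeatureSet, pond: SimplePolygon, buffer_m: float = 500.0) -> float:
    """Road length per unit area (m/m^2) in the pond's ring buffer."""
    buf = buffer_polygon(pond, buffer_m)
    return clip_length(roads, buf) / buf.area


def urban_ratio(
    landuse: FeatureSet | RasterGrid, pond: SimplePolygon, buffer_m: float = 500.0
) -> float:
    """Fraction of the ring buffer covered by urban land use.

    Accepts either urban polygons (exact areas) or a category raster
    (cell-count ratio, always in [0, 1]).
    """
    buf = buffer_polygon(pond, buffer_m)
    if isinstance(landuse, RasterGrid):
        codes = np.unique(landuse.values[~landuse.nodata_mask()]).astype(int)
        unknown = set(codes) - set(LANDUSE_CODES.values())
        if unknown:
            raise ValueError(f"unknown land-use category codes: {sorted(unknown)}")
        mask = rasterize_polygon(buf, landuse)
        n_buf = int(mask.sum())
        if n_buf == 0:
            return 0.0
        n_urban = int((landuse.values[mask] == LANDUSE_CODES["urban"]).sum())
        return n_urban / n_buf
    geom = buf.to_shapely()
    urban_area = 0.0
    for patch in landuse:
        if landuse.attributes.get(patch.id, {}).get("category", "urban") == "urban":
            urban_area += patch.to_shapely().intersection(geom).area
    return min(urban_area / geom.area, 1.0)


def river_density_profile(
    rivers: FeatureSet,
    pond: SimplePolygon,
    buffers: tuple[int, ...] = RIVER_BUFFERS,
) -> dict[int, float]:
    """River length per unit area (m/m^2) for each graded ring buffer."""
    if list(buffers) != sorted(set(buffers)) or min(buffers) <= 0:
        raise ValueError("buffers must be strictly increasing and positive")
    out: dict[int, float] = {}
    for b in buffers:
        buf = buffer_polygon(pond, b)
        out[b] = clip_length(rivers, buf) / buf.area
    return out


def connectivity_class(pond_id: str, graph: CanalGraph) -> int:
    """Connectivity with upstream reservoirs: 2 when reservoir water arrives
    through canals only; 1 when it arrives only via intermediate ponds or
    farmland; 0 when no reservoir reaches the pond.  Direct dominates."""
    if pond_id not in graph.node_kinds:
        raise KeyError(f"unknown pond id {pond_id!r}")
    g = graph.to_networkx()
    reservoirs = [n for n, k in graph.node_kinds.items() if k == "reservoir"]
    # direct: path whose intermediate nodes are canals only
    direct_nodes = [
        n
        for n, k in graph.node_kinds.items()
        if k in ("reservoir", "canal") or n == pond_id
    ]
    sub = g.subgraph(direct_nodes)
    for res in reservoirs:
        if nx.has_path(sub, res, pond_id):
            return 2
    for res in reservoirs:
        if nx.has_path(g, res, pond_id):
            return 1
    return 0


# ---------------------------------------------------------------------------
# feature-table assembly and CSV round trip
# ---------------------------------------------------------------------------

_DENSITY_SCALE = 1e3  # m/m^2 -> 1e-3 m/m^2 display unit


def _columns() -> list[str]:
    cols = ["pond_id", "visibility", "road_density_1e-3_m_per_m2", "urban_ratio"]
    cols += [f"river_density_{b}m_1e-3_m_per_m2" for b in RIVER_BUFFERS]
    cols += ["connectivity", "area_m2", "chl_a_ug_per_L", "drained",
             "present_bluegill", "present_bass"]
    return cols


def records_to_frame(records: list[PondRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "pond_id": r.pond_id,
            "visibility": r.visibility,
            "road_density_1e-3_m_per_m2": r.road_density * _DENSITY_SCALE,
            "urban_ratio": r.urban_ratio,
            "connectivity": r.connectivity,
            "area_m2": r.area,
            "chl_a_ug_per_L": r.chl_a,
            "drained": r.drained,
            "present_bluegill": r.present_bluegill,
            "present_bass": r.present_bass,
        }
        for b in RIVER_BUFFERS:
            row[f"river_density_{b}m_1e-3_m_per_m2"] = r.river_density[b] * _DENSITY_SCALE
        rows.append(row)
    return pd.DataFrame(rows, columns=_columns())


def frame_to_records(df: pd.DataFrame) -> list[PondRecord]:
    records = []
    for d in df.to_dict("records"):
        records.append(
            PondRecord(
                pond_id=str(d["pond_id"]),
                visibility=int(d["visibility"]),
                road_density=float(d["road_density_1e-3_m_per_m2"]) / _DENSITY_SCALE,
                urban_ratio=float(d["urban_ratio"]),
                river_density={
                    b: float(d[f"river_density_{b}m_1e-3_m_per_m2"]) / _DENSITY_SCALE
                    for b in RIVER_BUFFERS
                },
                connectivity=int(d["connectivity"]),
                area=float(d["area_m2"]),
                chl_a=float(d["chl_a_ug_per_L"]),
                drained=int(d["drained"]),
                present_bluegill=None if pd.isna(d["present_bluegill"]) else int(d["present_bluegill"]),
                present_bass=None if pd.isna(d["present_bass"]) else int(d["present_bass"]),
            )
        )
    return records


def assemble_feature_table(
    visibility_table: dict[str, int],
    road_densities: dict[str, float],
    urban_ratios: dict[str, float],
    river_profiles: dict[str, dict[int, float]],
    connectivity: dict[str, int],
    areas: dict[str, float],
    attributes: pd.DataFrame,
    labels: pd.DataFrame | None = None,
) -> list[PondRecord]:
    """Join the per-pond metric outputs into one record per pond.

    ``attributes`` must carry pond_id, chl_a, drained; ``labels`` optionally
    carries present_bluegill / present_bass.  Raises if any input is missing a
    pond or lists one twice.
    """
    attrs = attributes.set_index(attributes["pond_id"].astype(str))
    if attrs.index.has_duplicates:
        dupes = sorted(attrs.index[attrs.index.duplicated()])
        raise ValueError(f"duplicate pond ids in attributes: {dupes}")
    universe = sorted(visibility_table)
    inputs = {
        "visibility": visibility_table,
        "road_density": road_densities,
        "urban_ratio": urban_ratios,
        "river_density": river_profiles,
        "connectivity": connectivity,
        "area": areas,
        "attributes": {str(i): None for i in attrs.index},
    }
    for name, mapping in inputs.items():
        missing = [p for p in universe if p not in mapping]
        extra = [p for p in mapping if p not in universe]
        if missing or extra:
            raise ValueError(
                f"{name}: pond id mismatch (missing {missing}, unexpected {extra})"
            )
    if attrs["chl_a"].isna().any():
        bad = sorted(attrs.index[attrs["chl_a"].isna()])
        raise ValueError(f"missing chl_a for ponds: {bad}")
    lab = None
    if labels is not None:
        lab = labels.set_index(labels["pond_id"].astype(str))
    records = []
    for pid in universe:
        records.append(
            PondRecord(
                pond_id=pid,
                visibility=int(visibility_table[pid]),
                road_density=float(road_densities[pid]),
                urban_ratio=float(urban_ratios[pid]),
                river_density=dict(river_profiles[pid]),
                connectivity=int(connectivity[pid]),
                area=float(areas[pid]),
                chl_a=float(attrs.loc[pid, "chl_a"]),
                drained=int(attrs.loc[pid, "drained"]),
                present_bluegill=int(lab.loc[pid, "present_bluegill"]) if lab is not None else None,
                present_bass=int(lab.loc[pid, "present_bass"]) if lab is not None else None,
            )
        )
    return records
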