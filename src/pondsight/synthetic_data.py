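"""Synthetic study landscapes: terrain, roads, ponds, rivers, land use,
canal graphs, pond attributes, and planted presence labels.

The generator emulates the structure of a pond-dotted agricultural landscape:
rolling hills (Gaussian bumps), an urbanised southern strip with building
blocks that obstruct sight lines, a jittered road grid that is denser in the
urban strip, meandering rivers, ponds with log-uniform areas, a
reservoir-canal network wiring a configurable fraction of ponds directly or
indirectly to reservoirs, log-normal chlorophyll-a, and a Bernoulli drainage
flag.  Presence labels follow planted decision rules (species A: connected to
a reservoir OR visibility above a quantile threshold; species B: chlorophyll-a
below a quantile threshold AND a Bernoulli introduction event), then flip
independently with a label-noise rate.

All randomness flows from a single seed through named substreams, so any
component can be regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .landscape_io import FeatureSet, Polyline, RasterGrid, SimplePolygon
from .landscape_metrics import (
    LANDUSE_CODES,
    RIVER_BUFFERS,
    CanalGraph,
    PondRecord,
    assemble_feature_table,
    connectivity_class,
    records_to_frame,
    river_density_profile,
    road_density,
    urban_ratio,
)
from .visibility import (
    VisibilityParams,
    compute_viewshed_counts,
    generate_observer_points,
    pond_visibility,
)


@dataclass
class SyntheticConfig:
    """Study-landscape generation parameters.

    The full-resolution defaults mirror the study conditions (1 m cells, 64
    ponds, observation points every 100 m, 500 m sight radius);
    :meth:`coarse` scales the raster to 5 m cells and 200 ponds for
    desk-scale end-to-end runs.
    """

    seed: int = 0
    extent: float = 3000.0  # m, square landscape
    cell_size: float = 1.0
    # terrain: rolling hills
    n_hills: int = 12
    hill_height_range: tuple[float, float] = (5.0, 60.0)
    hill_radius_range: tuple[float, float] = (200.0, 700.0)
    # buildings inside urban land
    building_density: float = 0.15  # blocks per urban hectare
    building_height_range: tuple[float, float] = (5.0, 15.0)
    building_size_range: tuple[float, float] = (10.0, 30.0)
    # roads: jittered grid, denser in the urban strip
    road_spacing: float = 500.0
    road_spacing_urban: float = 250.0
    road_jitter: float = 30.0
    # ponds
    n_ponds: int = 64
    pond_area_range: tuple[float, float] = (685.0, 111_626.0)
    # rivers
    n_rivers: int = 3
    # reservoirs and canal wiring (fractions of ponds by connectivity class)
    n_reservoirs: int = 3
    frac_direct: float = 19 / 64
    frac_indirect: float = 14 / 64
    # land use mix (woodland / farmland / urban fractions, sum to 1) and the
    # width of the urbanised southern strip as a fraction of the extent
    landuse_mix: tuple[float, float, float] = (0.36, 0.46, 0.18)
    # pond attributes
    chl_a_log_mean: float = float(np.log(26.2))  # median 26.2 ug/L
    chl_a_log_sd: float = 1.3
    chl_a_range: tuple[float, float] = (1.9, 438.8)  # ug/L, clipped
    drained_prob: float = 27 / 64
    # planted presence rules
    visibility_quantile: float = 0.65  # species-A visibility threshold
    chl_quantile: float = 0.25  # species-B chl-a ceiling
    p_intro: float = 0.75  # species-B introduction probability
    noise_rate: float = 0.10
    # viewshed parameters used when building the feature table
    visibility_params: VisibilityParams = field(default_factory=VisibilityParams)

    def __post_init__(self) -> None:
        if abs(sum(self.landuse_mix) - 1.0) > 1e-9:
            raise ValueError("landuse_mix fractions must sum to 1")
        n_cells = self.extent / self.cell_size
        if abs(n_cells - round(n_cells)) > 1e-9:
            raise ValueError("extent must be a multiple of cell_size")

    @classmethod
    def coarse(cls, seed: int = 0, n_ponds: int = 200) -> "SyntheticConfig":
        """Desk-scale configuration: 5 m cells, smaller ponds, wider observer
        spacing, ray step equal to the cell size."""
        return cls(
            seed=seed,
            cell_size=5.0,
            n_ponds=n_ponds,
            pond_area_range=(400.0, 10_000.0),
            building_size_range=(15.0, 40.0),
            visibility_params=VisibilityParams(spacing=200.0, los_step=5.0),
        )

    def substream(self, name: str) -> np.random.Generator:
        key = zlib.crc32(name.encode("utf-8"))  # stable across processes
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class SyntheticLandscape:
    dsm: RasterGrid
    roads: FeatureSet
    rivers: FeatureSet
    ponds: FeatureSet
    landuse: RasterGrid
    canals: CanalGraph
    attrs: pd.DataFrame  # pond_id, chl_a, drained


# ---------------------------------------------------------------------------
# terrain
# ---------------------------------------------------------------------------


def generate_terrain(config: SyntheticConfig, landuse: RasterGrid | None = None) -> RasterGrid:
    """Smooth hills plus rectangular building blocks inside urban land.

    Without a land-use raster only the hill field is generated.
    """
    rng = config.substream("terrain")
    n = int(round(config.extent / config.cell_size))
    xs = (np.arange(n) + 0.5) * config.cell_size
    ys = (np.arange(n) + 0.5) * config.cell_size
    gx, gy = np.meshgrid(xs, ys)
    z = np.zeros((n, n))
    for _ in range(config.n_hills):
        cx, cy = rng.uniform(0, config.extent, size=2)
        h = rng.uniform(*config.hill_height_range)
        r = rng.uniform(*config.hill_radius_range)
        z += h * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * r**2))
    grid = RasterGrid(0.0, 0.0, config.cell_size, z)
    if landuse is not None:
        _add_buildings(config, grid, landuse)
    return grid


def _add_buildings(config: SyntheticConfig, dsm: RasterGrid, landuse: RasterGrid) -> None:
    rng = config.substream("buildings")
    urban = landuse.values == LANDUSE_CODES["urban"]
    urban_ha = urban.sum() * dsm.cell_size**2 / 1e4
    n_blocks = rng.poisson(config.building_density * urban_ha)
    rows, cols = np.nonzero(urban)
    if rows.size == 0 or n_blocks == 0:
        return
    for _ in range(n_blocks):
        i = rng.integers(rows.size)
        r, c = rows[i], cols[i]
        h = rng.uniform(*config.building_height_range)
        size = rng.uniform(*config.building_size_range)
        half = max(1, int(size / dsm.cell_size / 2))
        r0, r1 = max(0, r - half), min(dsm.n_rows, r + half)
        c0, c1 = max(0, c - half), min(dsm.n_cols, c + half)
        block = dsm.values[r0:r1, c0:c1]
        block += h * urban[r0:r1, c0:c1]


# ---------------------------------------------------------------------------
# land use, roads, rivers, ponds, canals
# ---------------------------------------------------------------------------


def _generate_landuse(config: SyntheticConfig) -> RasterGrid:
    """Urban strip along the southern ('coastal') edge, woodland patches in
    the remainder, farmland elsewhere, at the configured area fractions."""
    rng = config.substream("landuse")
    n = int(round(config.extent / config.cell_size))
    frac_wood, _frac_farm, frac_urban = config.landuse_mix
    vals = np.full((n, n), LANDUSE_CODES["farmland"], dtype=float)
    # urban strip: southern rows (row 0 is south)
    n_urban_rows = int(round(frac_urban * n))
    vals[:n_urban_rows, :] = LANDUSE_CODES["urban"]
    # woodland: blobby patches seeded in the non-urban zone
    target_wood = int(frac_wood * n * n)
    wood = np.zeros((n, n), dtype=bool)
    ys = np.arange(n)[:, None]
    xs = np.arange(n)[None, :]
    while wood.sum() < target_wood:
        cy = rng.uniform(n_urban_rows, n)
        cx = rng.uniform(0, n)
        r = rng.uniform(0.05 * n, 0.2 * n)
        wood |= ((xs - cx) ** 2 + (ys - cy) ** 2) < r**2
        wood[:n_urban_rows, :] = False
    vals[wood] = LANDUSE_CODES["woodland"]
    return RasterGrid(0.0, 0.0, config.cell_size, vals, nodata=-1.0)


def _generate_roads(config: SyntheticConfig) -> FeatureSet:
    rng = config.substream("roads")
    e = config.extent
    _, _, frac_urban = config.landuse_mix
    urban_top = frac_urban * e
    roads: list[Polyline] = []

    def jittered_line(fixed: float, axis: str, rid: str, spacing: float) -> Polyline:
        ticks = np.linspace(0, e, max(3, int(e / spacing) + 1))
        pts = []
        for t in ticks:
            j = rng.uniform(-config.road_jitter, config.road_jitter)
            v = float(np.clip(fixed + j, 1.0, e - 1.0))
            pts.append((t, v) if axis == "h" else (v, t))
        return Polyline(rid, pts)

    k = 0
    for pos in np.arange(config.road_spacing / 2, e, config.road_spacing):
        roads.append(jittered_line(pos, "h", f"road_h{k}", config.road_spacing))
        roads.append(jittered_line(pos, "v", f"road_v{k}", config.road_spacing))
        k += 1
    # extra east-west roads inside the urban strip
    for pos in np.arange(config.road_spacing_urban / 2, urban_top, config.road_spacing_urban):
        if pos % config.road_spacing == config.road_spacing / 2:
            continue
        roads.append(jittered_line(pos, "h", f"road_u{k}", config.road_spacing_urban))
        k += 1
    return FeatureSet("roads", roads)


def _generate_rivers(config: SyntheticConfig) -> FeatureSet:
    rng = config.substream("rivers")
    e = config.extent
    rivers = []
    for i in range(config.n_rivers):
        x = rng.uniform(0.1 * e, 0.9 * e)
        pts = [(x, 0.0)]
        y = 0.0
        while y < e:
            y = min(e, y + rng.uniform(0.05 * e, 0.15 * e))
            x = float(np.clip(x + rng.normal(0, 0.05 * e), 1.0, e - 1.0))
            pts.append((x, y))
        rivers.append(Polyline(f"river_{i}", pts))
    return FeatureSet("rivers", rivers)


def _generate_ponds(config: SyntheticConfig) -> FeatureSet:
    """Non-overlapping rectangular ponds with log-uniform areas."""
    rng = config.substream("ponds")
    e = config.extent
    lo, hi = config.pond_area_range
    ponds: list[SimplePolygon] = []
    boxes: list[tuple[float, float, float, float]] = []
    attempts = 0
    margin = 10.0
    while len(ponds) < config.n_ponds:
        attempts += 1
        if attempts > 200 * config.n_ponds:
            raise RuntimeError(
                f"could not place {config.n_ponds} disjoint ponds in a "
                f"{e:g} m extent; reduce the count or the area range"
            )
        area = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        aspect = rng.uniform(0.6, 1.6)
        w = float(np.sqrt(area * aspect))
        h = area / w
        x0 = rng.uniform(margin, e - w - margin)
        y0 = rng.uniform(margin, e - h - margin)
        box = (x0 - margin, y0 - margin, x0 + w + margin, y0 + h + margin)
        if any(
            not (box[2] < b[0] or b[2] < box[0] or box[3] < b[1] or b[3] < box[1])
            for b in boxes
        ):
            continue
        boxes.append(box)
        pid = f"pond_{len(ponds):03d}"
        ponds.append(
            SimplePolygon(pid, [(x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h), (x0, y0)])
        )
    return FeatureSet("ponds", ponds)


def _generate_canals(config: SyntheticConfig, pond_ids: list[str]) -> CanalGraph:
    """Wire a configured fraction of ponds to reservoirs: direct ponds reach a
    reservoir through canal nodes only; indirect ponds receive water through a
    direct pond or a farmland node."""
    rng = config.substream("canals")
    kinds: dict[str, str] = {p: "pond" for p in pond_ids}
    edges: list[tuple[str, str]] = []
    reservoirs = [f"res_{i}" for i in range(config.n_reservoirs)]
    for r in reservoirs:
        kinds[r] = "reservoir"
    n = len(pond_ids)
    perm = rng.permutation(n)
    n_direct = int(round(config.frac_direct * n))
    n_indirect = int(round(config.frac_indirect * n))
    direct = [pond_ids[i] for i in perm[:n_direct]]
    indirect = [pond_ids[i] for i in perm[n_direct : n_direct + n_indirect]]
    ci = 0
    for p in direct:
        res = reservoirs[rng.integers(len(reservoirs))]
        canal = f"canal_{ci}"
        ci += 1
        kinds[canal] = "canal"
        edges += [(res, canal), (canal, p)]
    fi = 0
    for p in indirect:
        # half via an upstream direct pond, half via farmland fed by a canal
        if direct and rng.random() < 0.5:
            up = direct[rng.integers(len(direct))]
            canal = f"canal_{ci}"
            ci += 1
            kinds[canal] = "canal"
            edges += [(up, canal), (canal, p)]
        else:
            res = reservoirs[rng.integers(len(reservoirs))]
            canal = f"canal_{ci}"
            ci += 1
            farm = f"farm_{fi}"
            fi += 1
            kinds[canal] = "canal"
            kinds[farm] = "farmland"
            edges += [(res, canal), (canal, farm), (farm, p)]
    return CanalGraph(edges, kinds)


def _generate_attrs(config: SyntheticConfig, pond_ids: list[str]) -> pd.DataFrame:
    rng = config.substream("attributes")
    chl = np.exp(rng.normal(config.chl_a_log_mean, config.chl_a_log_sd, len(pond_ids)))
    chl = np.clip(chl, *config.chl_a_range)
    drained = (rng.random(len(pond_ids)) < config.drained_prob).astype(int)
    return pd.DataFrame({"pond_id": pond_ids, "chl_a": chl, "drained": drained})


def generate_landscape(config: SyntheticConfig) -> SyntheticLandscape:
    """Generate all landscape components for one seed."""
    landuse = _generate_landuse(config)
    dsm = generate_terrain(config, landuse)
    roads = _generate_roads(config)
    rivers = _generate_rivers(config)
    ponds = _generate_ponds(config)
    pond_ids = [p.id for p in ponds]
    canals = _generate_canals(config, pond_ids)
    attrs = _generate_attrs(config, pond_ids)
    return SyntheticLandscape(dsm, roads, rivers, ponds, landuse, canals, attrs)


# ---------------------------------------------------------------------------
# planted presence rules
# ---------------------------------------------------------------------------


@dataclass
class PresenceRules:
    """Planted decision rules; thresholds are resolved against the generated
    feature marginals (quantiles) and recorded for recovery checks."""

    visibility_threshold: float
    chl_threshold: float
    p_intro: float
    noise_rate: float


def resolve_rules(features: list[PondRecord], config: SyntheticConfig) -> PresenceRules:
    vis = np.array([r.visibility for r in features], dtype=float)
    chl = np.array([r.chl_a for r in features], dtype=float)
    return PresenceRules(
        visibility_threshold=float(np.quantile(vis, config.visibility_quantile)),
        chl_threshold=float(np.quantile(chl, config.chl_quantile)),
        p_intro=config.p_intro,
        noise_rate=config.noise_rate,
    )


def simulate_presence(
    features: list[PondRecord],
    rules: PresenceRules,
    noise_rate: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Label ponds by the planted rules, then flip each label independently
    with probability ``noise_rate``."""
    rng = np.random.default_rng(seed)
    noise = rules.noise_rate if noise_rate is None else noise_rate
    rows = []
    for r in features:
        a = int(r.connectivity >= 1 or r.visibility >= rules.visibility_threshold)
        b = int(r.chl_a <= rules.chl_threshold and rng.random() < rules.p_intro)
        if rng.random() < noise:
            a = 1 - a
        if rng.random() < noise:
            b = 1 - b
        rows.append({"pond_id": r.pond_id, "present_bluegill": a, "present_bass": b})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end study dataset
# ---------------------------------------------------------------------------


def compute_features(landscape: SyntheticLandscape, params: VisibilityParams) -> list[PondRecord]:
    """Run the viewshed engine and landscape metrics over a landscape."""
    observers = generate_observer_points(landscape.roads, landscape.dsm, params)
    counts = compute_viewshed_counts(landscape.dsm, observers, params)
    vis = {p.id: pond_visibility(counts, p) for p in landscape.ponds}
    roadd = {p.id: road_density(landscape.roads, p) for p in landscape.ponds}
    urb = {p.id: urban_ratio(landscape.landuse, p) for p in landscape.ponds}
    rivers = {
        p.id: river_density_profile(landscape.rivers, p) for p in landscape.ponds
    }
    conn = {p.id: connectivity_class(p.id, landscape.canals) for p in landscape.ponds}
    areas = {p.id: p.area for p in landscape.ponds}
    return assemble_feature_table(vis, roadd, urb, rivers, conn, areas, landscape.attrs)


def generate_study_dataset(
    config: SyntheticConfig,
) -> tuple[SyntheticLandscape, pd.DataFrame, PresenceRules]:
    """Landscape + labelled feature table + the planted rules used."""
    landscape = generate_landscape(config)
    features = compute_features(landscape, config.visibility_params)
    rules = resolve_rules(features, config)
    label_seed = int(config.substream("labels").integers(2**31))
    labels = simulate_presence(features, rules, seed=label_seed)
    lab = labels.set_index("pond_id")
    for r in features:
        r.present_bluegill = int(lab.loc[r.pond_id, "present_bluegill"])
        r.present_bass = int(lab.loc[r.pond_id, "present_bass"])
    return landscape, records_to_frame(features), rules


def config_provenance(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["visibility_params"] = asdict(config.visibility_params)
    return d
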