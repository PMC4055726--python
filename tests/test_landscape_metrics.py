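import numpy as np
import pandas as pd
import pytest

from pondsight import (
    CanalGraph,
    FeatureSet,
    Polyline,
    RasterGrid,
    SimplePolygon,
    assemble_feature_table,
    buffer_polygon,
    clip_length,
    connectivity_class,
    frame_to_records,
    records_to_frame,
    river_density_profile,
    road_density,
    trophic_class,
    urban_ratio,
)
from pondsight.landscape_metrics import LANDUSE_CODES, RIVER_BUFFERS


@pytest.fixture
def pond():
    return SimplePolygon("p", [(0, 0), (100, 0), (100, 100), (0, 100), (0, 0)])


class TestRoadDensity:
    def test_no_roads_zero(self, pond):
        assert road_density(FeatureSet("roads", []), pond) == 0

    def test_single_straight_road_analytic(self, pond):
        # horizontal road at y = 50 spanning well past the buffer: clipped
        # length equals the ring-buffer width at that y = 2 * 500
        roads = FeatureSet("roads", [Polyline("r", [(-2000, 50), (2000, 50)])])
        buf = buffer_polygon(pond, 500)
        expected = 2 * 500 / buf.area
        assert road_density(roads, pond) == pytest.approx(expected, rel=1e-6)

    def test_duplicated_roads_double_density(self, pond):
        roads1 = FeatureSet("roads", [Polyline("r", [(-2000, 50), (2000, 50)])])
        roads2 = FeatureSet(
            "roads",
            [
                Polyline("r", [(-2000, 50), (2000, 50)]),
                Polyline("r2", [(-2000, 50), (2000, 50)]),
            ],
        )
        assert road_density(roads2, pond) == pytest.approx(2 * road_density(roads1, pond))


class TestUrbanRatio:
    def test_all_urban_is_one(self, pond):
        n = 300
        grid = RasterGrid(-1000, -1000, 10, np.full((n, n), LANDUSE_CODES["urban"], float))
        assert urban_ratio(grid, pond) == 1.0

    def test_no_urban_is_zero(self, pond):
        n = 300
        grid = RasterGrid(-1000, -1000, 10, np.full((n, n), LANDUSE_CODES["farmland"], float))
        assert urban_ratio(grid, pond) == 0.0

    def test_half_plane_symmetry(self, pond):
        # urban half-plane x >= 50 covers exactly half the centered buffer
        n = 1200
        vals = np.full((n, n), LANDUSE_CODES["farmland"], float)
        grid = RasterGrid(-1000, -1000, 2.0, vals)
        xs, _ = grid.cell_centers()
        vals[:, xs >= 50] = LANDUSE_CODES["urban"]
        assert urban_ratio(grid, pond) == pytest.approx(0.5, abs=0.01)

    def test_unknown_code_rejected(self, pond):
        grid = RasterGrid(-1000, -1000, 10, np.full((300, 300), 99.0))
        with pytest.raises(ValueError, match="99"):
            urban_ratio(grid, pond)

    def test_polygon_and_raster_representations_agree(self, pond):
        patch = SimplePolygon("u", [(200, -600), (600, -600), (600, 600), (200, 600), (200, -600)])
        polys = FeatureSet("landuse", [patch], {"u": {"category": "urban"}})
        exact = urban_ratio(polys, pond)
        n = 2400
        vals = np.full((n, n), LANDUSE_CODES["farmland"], float)
        grid = RasterGrid(-1000, -1000, 1.0, vals)
        xs, ys = grid.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        vals[(gx >= 200) & (gx <= 600) & (gy >= -600) & (gy <= 600)] = LANDUSE_CODES["urban"]
        approx = urban_ratio(grid, pond)
        buf = buffer_polygon(pond, 500)
        tol = 2 * buf.to_shapely().length * 1.0 / buf.area
        assert abs(exact - approx) <= tol


class TestRiverDensity:
    def test_no_rivers_all_zero(self, pond):
        prof = river_density_profile(FeatureSet("rivers", []), pond)
        assert set(prof) == set(RIVER_BUFFERS)
        assert all(v == 0 for v in prof.values())

    def test_far_river_only_in_large_buffers(self, pond):
        # straight river 300 m from the pond edge
        rivers = FeatureSet("rivers", [Polyline("rv", [(-5000, -300), (5000, -300)])])
        prof = river_density_profile(rivers, pond)
        for b in (5, 10, 25, 50, 100, 250):
            assert prof[b] == 0
        for b in (500, 1000):
            assert prof[b] > 0
        # analytic check at 500 m: the line y=-300 crosses the ring buffer
        buf = buffer_polygon(pond, 500).to_shapely()
        from shapely.geometry import LineString

        expected = LineString([(-5000, -300), (5000, -300)]).intersection(buf).length / buf.area
        assert prof[500] == pytest.approx(expected, rel=1e-9)

    def test_translation_invariance(self, pond):
        rivers = FeatureSet("rivers", [Polyline("rv", [(-900, -300), (900, 400)])])
        prof0 = river_density_profile(rivers, pond)
        dx, dy = 12345.0, -6789.0
        pond2 = SimplePolygon("p2", [(x + dx, y + dy) for x, y in pond.exterior])
        rivers2 = FeatureSet(
            "rivers", [Polyline("rv", [(x + dx, y + dy) for x, y in rivers.get("rv").vertices])]
        )
        prof2 = river_density_profile(rivers2, pond2)
        for b in RIVER_BUFFERS:
            assert prof2[b] == pytest.approx(prof0[b], rel=1e-9, abs=1e-15)

    def test_bad_buffer_sequence_rejected(self, pond):
        with pytest.raises(ValueError):
            river_density_profile(FeatureSet("rivers", []), pond, buffers=(10, 5))


class TestConnectivity:
    def graph(self, edges, kinds):
        return CanalGraph(edges, kinds)

    def test_direct_via_canal(self):
        g = self.graph(
            [("res", "c1"), ("c1", "pondA")],
            {"res": "reservoir", "c1": "canal", "pondA": "pond"},
        )
        assert connectivity_class("pondA", g) == 2

    def test_indirect_via_upstream_pond(self):
        g = self.graph(
            [("res", "c1"), ("c1", "pondA"), ("pondA", "c2"), ("c2", "pondB")],
            {"res": "reservoir", "c1": "canal", "c2": "canal", "pondA": "pond", "pondB": "pond"},
        )
        assert connectivity_class("pondA", g) == 2
        assert connectivity_class("pondB", g) == 1

    def test_indirect_via_farmland(self):
        g = self.graph(
            [("res", "c1"), ("c1", "farm"), ("farm", "pondA")],
            {"res": "reservoir", "c1": "canal", "farm": "farmland", "pondA": "pond"},
        )
        assert connectivity_class("pondA", g) == 1

    def test_isolated_pond(self):
        g = self.graph([], {"res": "reservoir", "pondA": "pond"})
        assert connectivity_class("pondA", g) == 0

    def test_direct_dominates_mediated_path(self):
        g = self.graph(
            [
                ("res", "c1"), ("c1", "pondA"), ("pondA", "c2"), ("c2", "pondB"),
                ("res", "c3"), ("c3", "pondB"),
            ],
            {
                "res": "reservoir", "c1": "canal", "c2": "canal", "c3": "canal",
                "pondA": "pond", "pondB": "pond",
            },
        )
        assert connectivity_class("pondB", g) == 2

    def test_monotone_under_edge_addition(self):
        kinds = {"res": "reservoir", "c1": "canal", "c2": "canal", "pondA": "pond", "pondB": "pond"}
        g0 = self.graph([("res", "c1"), ("c1", "pondA")], kinds)
        g1 = self.graph([("res", "c1"), ("c1", "pondA"), ("res", "c2"), ("c2", "pondB")], kinds)
        assert connectivity_class("pondB", g1) >= connectivity_class("pondB", g0)
        assert connectivity_class("pondA", g1) == connectivity_class("pondA", g0) == 2

    def test_unknown_pond_rejected(self):
        g = self.graph([], {"res": "reservoir"})
        with pytest.raises(KeyError):
            connectivity_class("ghost", g)

    def test_csv_round_trip_preserves_isolated_nodes(self, tmp_path):
        g = self.graph(
            [("res", "c1"), ("c1", "pondA")],
            {"res": "reservoir", "c1": "canal", "pondA": "pond", "pondB": "pond"},
        )
        p = tmp_path / "canals.csv"
        g.to_csv(p)
        back = CanalGraph.from_csv(p)
        assert back.node_kinds == g.node_kinds
        assert back.edges == g.edges
        assert connectivity_class("pondB", back) == 0


class TestTrophicClass:
    @pytest.mark.parametrize(
        "chl,expected",
        [
            (26.2, "hypertrophic"),
            (38.25, "hypertrophic"),
            (25.0, "hypertrophic"),
            (24.99, "eutrophic"),
            (8.0, "eutrophic"),
            (7.9, "sub_eutrophic"),
        ],
    )
    def test_thresholds(self, chl, expected):
        assert trophic_class(chl) == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            trophic_class(0.0)


class TestAssemble:
    def make_inputs(self, ids):
        vis = {i: 10 for i in ids}
        rd = {i: 0.01 for i in ids}
        ur = {i: 0.2 for i in ids}
        rp = {i: {b: 0.0 for b in RIVER_BUFFERS} for i in ids}
        conn = {i: 0 for i in ids}
        area = {i: 5000.0 for i in ids}
        attrs = pd.DataFrame({"pond_id": ids, "chl_a": [20.0] * len(ids), "drained": [0] * len(ids)})
        return vis, rd, ur, rp, conn, area, attrs

    def test_cardinality(self):
        ids = [f"p{i:02d}" for i in range(64)]
        records = assemble_feature_table(*self.make_inputs(ids))
        assert len(records) == 64

    def test_missing_chl_names_pond(self):
        ids = ["a", "b"]
        vis, rd, ur, rp, conn, area, attrs = self.make_inputs(ids)
        attrs.loc[attrs.pond_id == "b", "chl_a"] = np.nan
        with pytest.raises(ValueError, match="b"):
            assemble_feature_table(vis, rd, ur, rp, conn, area, attrs)

    def test_missing_pond_in_one_input_names_it(self):
        ids = ["a", "b"]
        vis, rd, ur, rp, conn, area, attrs = self.make_inputs(ids)
        del conn["b"]
        with pytest.raises(ValueError, match="connectivity"):
            assemble_feature_table(vis, rd, ur, rp, conn, area, attrs)

    def test_csv_round_trip(self, tmp_path):
        ids = ["a", "b", "c"]
        records = assemble_feature_table(*self.make_inputs(ids))
        for i, r in enumerate(records):
            r.present_bluegill = i % 2
            r.present_bass = 0
            r.road_density = 0.00123 + i * 1e-4
        df = records_to_frame(records)
        p = tmp_path / "features.csv"
        df.to_csv(p, index=False)
        back = frame_to_records(pd.read_csv(p))
        for r0, r1 in zip(records, back):
            assert r0.pond_id == r1.pond_id
            assert r0.road_density == pytest.approx(r1.road_density, rel=1e-12)
            assert r0.river_density == r1.river_density
            assert r0.present_bluegill == r1.present_bluegill
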