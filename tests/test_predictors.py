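"""GIS predictor extraction against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airlur.predictors import (
    MINIMAL_FLOW,
    CoverageError,
    NoRoadOfClass,
    PredictorConfig,
    RoadClassRule,
    assign_minimal_flow,
    buffer_fraction,
    buffer_population,
    buffer_traffic,
    build_predictor_table,
    classify_road,
    expected_column_count,
    flow_within,
    nearest_road,
)
from airlur.types import LandUseGrid, PopulationGrid, RoadNetwork, RoadSegment

from conftest import make_site_table


def seg(vertices, flow=1000.0, heavy=0.1, authority="municipal", data=True, id="s"):
    return RoadSegment(id, np.asarray(vertices, float), flow, heavy, authority, data)


def random_network(rng, n=8, extent=1000.0):
    segs = []
    for i in range(n):
        k = rng.integers(2, 5)
        pts = rng.uniform(0, extent, size=(k, 2))
        segs.append(seg(pts, flow=float(rng.uniform(500, 20000)), id=f"r{i}"))
    return RoadNetwork(segs)


# --------------------------------------------------------------- oracles

def point_segment_distance(p, a, b):
    """Closed-form point-to-segment distance (projection formula)."""
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.hypot(*(a + t * ab - p)))


def brute_nearest(network, point):
    best, bd = None, math.inf
    for s in network:
        for a, b in zip(s.vertices[:-1], s.vertices[1:]):
            d = point_segment_distance(point, a, b)
            if d < bd:
                best, bd = s, d
    return bd, best


def integrate_buffer_traffic(network, point, radius, step=0.1):
    """Discretised line integral of flow over in-disc road length."""
    total = 0.0
    for s in network:
        for a, b in zip(s.vertices[:-1], s.vertices[1:]):
            length = float(np.hypot(*(b - a)))
            if length == 0:
                continue
            n = max(int(length / step), 1)
            t = (np.arange(n) + 0.5) / n
            pts = a + t[:, None] * (b - a)
            inside = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1]) <= radius
            total += s.flow * inside.mean() * length
    return total


# ----------------------------------------------------------------- tests

class TestMinimalFlow:
    def test_counted_segment_untouched(self):
        net = RoadNetwork([seg([[0, 0], [1, 0]], flow=8000.0, data=True)])
        out = assign_minimal_flow(net, 1225.0)
        assert out.segments[0].flow == 8000.0

    def test_uncounted_segment_gets_minimal_flow(self):
        net = RoadNetwork([seg([[0, 0], [1, 0]], flow=9999.0, data=False)])
        out = assign_minimal_flow(net)
        assert out.segments[0].flow == MINIMAL_FLOW == 1225.0

    def test_exactly_the_flagged_segments_change(self):
        rng = np.random.default_rng(0)
        segs = [
            seg([[i, 0], [i + 1, 0]], flow=float(rng.uniform(2000, 9000)), data=(i >= 4), id=f"s{i}")
            for i in range(10)
        ]
        out = assign_minimal_flow(RoadNetwork(segs))
        changed = sum(a.flow != b.flow for a, b in zip(segs, out))
        assert changed == 4
        # original network untouched (copy semantics)
        assert all(s.flow > 1225.0 for s in segs[:4])


class TestRoadClasses:
    @pytest.mark.parametrize(
        "flow,expected",
        [
            (4999.0, {"all"}),
            (5000.0, {"all", "busy"}),
            (9999.0, {"all", "busy"}),
            (12000.0, {"all", "busy", "main"}),
        ],
    )
    def test_thresholds_inclusive(self, flow, expected):
        assert classify_road(seg([[0, 0], [1, 0]], flow=flow)) == expected

    def test_national_roads_are_freeways(self):
        s = seg([[0, 0], [1, 0]], flow=30000.0, authority="national")
        assert classify_road(s) == {"all", "busy", "main", "freeway"}

    @given(flow=st.floats(min_value=0, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_classes_are_nested(self, flow):
        classes = classify_road(seg([[0, 0], [1, 0]], flow=flow))
        assert "all" in classes
        if "main" in classes:
            assert "busy" in classes

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            RoadClassRule(busy_threshold=10000.0, main_threshold=5000.0)


class TestNearestRoad:
    def test_point_on_segment(self):
        net = RoadNetwork([seg([[0, 0], [100, 0]], flow=3000.0)])
        d, flow, heavy = nearest_road(net, (50.0, 0.0))
        assert d == 0.0 and flow == 3000.0

    def test_perpendicular_distance(self):
        net = RoadNetwork([seg([[-100, 0], [100, 0]], flow=3000.0, heavy=0.2)])
        d, flow, heavy = nearest_road(net, (0.0, 10.0))
        assert d == pytest.approx(10.0)
        assert heavy == pytest.approx(600.0)

    def test_no_road_of_class_is_explicit(self):
        net = RoadNetwork([seg([[0, 0], [1, 0]], flow=100.0)])
        with pytest.raises(NoRoadOfClass):
            nearest_road(net, (0.0, 0.0), "busy")

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            net = random_network(rng)
            p = tuple(rng.uniform(0, 1000, size=2))
            d, flow, _ = nearest_road(net, p)
            od, oseg = brute_nearest(net, p)
            assert d == pytest.approx(od, abs=1e-6)
            assert flow == oseg.flow


class TestFlowWithin:
    def test_beyond_cutoff_is_zero(self):
        net = RoadNetwork([seg([[-500, 60], [500, 60]], flow=7000.0)])
        assert flow_within(net, (0.0, 0.0), "busy", 50.0) == 0.0

    def test_inside_cutoff_returns_flow(self):
        net = RoadNetwork([seg([[-500, 30], [500, 30]], flow=7000.0)])
        assert flow_within(net, (0.0, 0.0), "busy", 50.0) == 7000.0

    def test_nearest_not_largest(self):
        near = seg([[-500, 20], [500, 20]], flow=6000.0, id="near")
        far = seg([[-500, 40], [500, 40]], flow=20000.0, id="far")
        assert flow_within(RoadNetwork([near, far]), (0.0, 0.0), "busy", 50.0) == 6000.0

    def test_cutoff_nesting(self):
        net = RoadNetwork([seg([[-500, 30], [500, 30]], flow=7000.0)])
        v25 = flow_within(net, (0.0, 0.0), "busy", 25.0)
        v50 = flow_within(net, (0.0, 0.0), "busy", 50.0)
        assert v25 == 0.0 and v50 == 7000.0


class TestBufferTraffic:
    def test_empty_buffer(self):
        net = RoadNetwork([seg([[500, 500], [600, 600]], flow=5000.0)])
        assert buffer_traffic(net, (0.0, 0.0), 100.0) == 0.0

    def test_chord_through_center(self):
        net = RoadNetwork([seg([[-10000, 0], [10000, 0]], flow=4000.0)])
        r = 100.0
        got = buffer_traffic(net, (0.0, 0.0), r)
        assert got == pytest.approx(4000.0 * 2 * r, rel=1e-3)

    def test_matches_line_integration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            net = random_network(rng, n=5)
            p = tuple(rng.uniform(200, 800, size=2))
            got = buffer_traffic(net, p, 100.0)
            want = integrate_buffer_traffic(net, p, 100.0)
            assert got == pytest.approx(want, rel=5e-3, abs=1.0)

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(8)
        net = random_network(rng, n=6)
        p = (500.0, 500.0)
        vals = [buffer_traffic(net, p, r) for r in (50, 100, 200, 400)]
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))


class TestBufferFraction:
    def test_uniform_grid(self):
        grid = LandUseGrid((0, 0), 100.0, np.ones((30, 30), np.int32), {1: "residential"})
        assert buffer_fraction(grid, (1500.0, 1500.0), 300.0, 1) == 1.0

    def test_absent_category(self):
        grid = LandUseGrid((0, 0), 100.0, np.ones((30, 30), np.int32), {1: "residential", 2: "water"})
        assert buffer_fraction(grid, (1500.0, 1500.0), 300.0, 2) == 0.0

    def test_outside_coverage_raises(self):
        grid = LandUseGrid((0, 0), 100.0, np.ones((10, 10), np.int32), {1: "residential"})
        with pytest.raises(CoverageError):
            buffer_fraction(grid, (5000.0, 5000.0), 300.0, 1)

    def test_matches_monte_carlo_oracle(self):
        from scipy import ndimage

        rng = np.random.default_rng(9)
        for _ in range(50):
            # spatially coherent categorical field, like real land cover
            scores = ndimage.gaussian_filter(rng.standard_normal((3, 40, 40)), sigma=(0, 3, 3))
            cats = (np.argmax(scores, axis=0) + 1).astype(np.int32)
            grid = LandUseGrid((0, 0), 100.0, cats, {1: "a", 2: "b", 3: "c"})
            p = tuple(rng.uniform(1000, 3000, size=2))
            got = buffer_fraction(grid, p, 300.0, 2)
            # Monte-Carlo disc sampling resolved to cell membership
            n = 100_000
            ang = rng.uniform(0, 2 * np.pi, n)
            rad = 300.0 * np.sqrt(rng.uniform(0, 1, n))
            xs = p[0] + rad * np.cos(ang)
            ys = p[1] + rad * np.sin(ang)
            cols = np.clip((xs / 100.0).astype(int), 0, 39)
            rows = np.clip(((4000.0 - ys) / 100.0).astype(int), 0, 39)
            want = float(np.mean(cats[rows, cols] == 2))
            assert abs(got - want) < 0.02


class TestBufferPopulation:
    def test_zero_raster(self):
        grid = PopulationGrid((0, 0), 100.0, np.zeros((20, 20)))
        assert buffer_population(grid, (1000.0, 1000.0), 300.0) == 0.0

    def test_uniform_density_scales_with_area(self):
        rho = 50.0
        grid = PopulationGrid((0, 0), 100.0, np.full((100, 100), rho))
        r = 2000.0
        got = buffer_population(grid, (5000.0, 5000.0), r)
        want = rho * math.pi * r**2 / 100.0**2
        assert got == pytest.approx(want, rel=0.02)

    def test_single_populated_cell(self):
        counts = np.zeros((20, 20))
        counts[10, 10] = 123.0
        grid = PopulationGrid((0, 0), 100.0, counts)
        # cell (10, 10) centre: x = 1050, y = 2000 - 1050 = 950
        assert buffer_population(grid, (1050.0, 950.0), 150.0) == 123.0


class TestPredictorTable:
    @pytest.fixture(scope="class")
    def scene(self):
        busy = seg([[-2000, 0], [2000, 0]], flow=9000.0, authority="provincial", id="busy")
        quiet = seg([[-2000, 500], [2000, 500]], flow=800.0, id="quiet")
        net = RoadNetwork([busy, quiet])
        grid = LandUseGrid((-2000, -2000), 100.0, np.ones((40, 40), np.int32), {1: "residential"})
        pop = PopulationGrid((-2000, -2000), 100.0, np.full((40, 40), 10.0))
        return net, grid, pop

    def test_zero_distance_is_clamped_in_log(self, scene):
        net, grid, pop = scene
        sites = make_site_table([(0.0, 0.0)], ["traffic"])
        table = build_predictor_table(sites, net, grid, pop, PredictorConfig(landuse_radii=(300.0,)))
        assert table["logdist_busy"].iloc[0] == pytest.approx(math.log(1.0))

    def test_absent_class_censored_not_missing(self, scene):
        net, grid, pop = scene  # no national segment -> no freeway
        sites = make_site_table([(0.0, 100.0)], ["urban_background"])
        table = build_predictor_table(sites, net, grid, pop, PredictorConfig(landuse_radii=(300.0,)))
        diag = math.hypot(4000.0, 4000.0)
        assert table["logdist_freeway"].iloc[0] == pytest.approx(math.log(diag))
        assert table["flow_near_freeway"].iloc[0] == 0.0
        assert not table.isna().any().any()

    def test_column_count_matches_closed_form(self, scene):
        net, grid, pop = scene
        config = PredictorConfig(landuse_radii=(300.0, 1000.0))
        sites = make_site_table([(0.0, 100.0), (100.0, 300.0)], ["traffic", "urban_background"])
        table = build_predictor_table(sites, net, grid, pop, config)
        assert table.shape[1] == expected_column_count(config, n_categories=1)

    def test_site_outside_rasters_raises(self, scene):
        net, grid, pop = scene
        sites = make_site_table([(9000.0, 9000.0)], ["rural"])
        with pytest.raises(CoverageError):
            build_predictor_table(sites, net, grid, pop, PredictorConfig())

    def test_within_cutoff_columns_consistent_with_nearest(self, scene):
        net, grid, pop = scene
        sites = make_site_table([(0.0, 60.0)], ["urban_background"])
        table = build_predictor_table(sites, net, grid, pop, PredictorConfig(landuse_radii=(300.0,)))
        # busy road at 60 m: beyond the 50 m cutoff, inside the 100 m one
        assert table["flow_near_busy_within_50"].iloc[0] == 0.0
        assert table["flow_near_busy_within_100"].iloc[0] == 9000.0
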