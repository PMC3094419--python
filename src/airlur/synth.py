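"""Synthetic study-region generator and concentration simulator.

Stands in for the two (undeposited) monitoring campaigns: a planar region
with national/provincial/municipal roads, categorical land use at fine and
coarse resolution, a population raster, monitoring sites placed under a
facade or curbside protocol, and per-period NO2 concentrations drawn from a
known ground-truth process (regional background + exponentially decaying
local traffic + land-use terms + season + noise).

Default campaign designs mirror the two field campaigns: a 60-site
large-area campaign (18 traffic / 34 urban background / 8 rural, plus 8
rural sites outside the study border) with four 1-week periods and 10.6%
sampler loss, and a 62-site city campaign (25 traffic / 37 non-traffic)
with thirteen 28-day periods and 3.7% loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

from .types import (
    GroundTruthParams,
    LandUseGrid,
    PopulationGrid,
    Region,
    RoadNetwork,
    RoadSegment,
    period_columns,
)

LANDUSE_CODES = {
    1: "residential",
    2: "industry",
    3: "port",
    4: "urban_green",
    5: "agriculture",
    6: "water",
}

#: fraction of managed road length with a supplied traffic count, by
#: authority (national counts are near-complete; municipal coverage is not).
COUNT_COVERAGE = {"national": 0.94, "provincial": 0.58, "municipal": 0.48}


@dataclass
class RegionConfig:
    """Parameters of the generated region.

    Extent is deliberately modest (8 x 8 km) so that a full two-campaign
    study runs in seconds; densities are km of road per km^2 and produce a
    dense urban-mix network in that extent.
    """

    width: float = 8000.0
    height: float = 8000.0
    road_density: dict[str, float] = field(
        default_factory=lambda: {"national": 0.15, "provincial": 0.35, "municipal": 1.2}
    )
    flow_median: dict[str, float] = field(
        default_factory=lambda: {"national": 30000.0, "provincial": 9000.0, "municipal": 2500.0}
    )
    flow_sigma: float = 0.5  # lognormal sigma of flows around the class median
    heavy_fraction_mean: dict[str, float] = field(
        default_factory=lambda: {"national": 0.15, "provincial": 0.10, "municipal": 0.05}
    )
    cell_size: float = 20.0  # fine land-use raster (city dialect)
    coarse_factor: int = 5  # coarse raster cell = factor * cell_size
    population_cell: float = 100.0
    population_total: float = 150000.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("region extent must be positive")
        if self.cell_size <= 0 or self.population_cell <= 0:
            raise ValueError("raster resolution must be positive")


@dataclass
class CampaignConfig:
    """Design of one monitoring campaign."""

    site_counts: dict[str, int] = field(
        default_factory=lambda: {"traffic": 18, "urban_background": 34, "rural": 8, "rural_external": 8}
    )
    protocol: str = "facade"
    id_prefix: str = ""
    n_periods: int = 4
    missing_rate: float = 0.106
    facade_offset: float = 10.0  # metres from road centreline
    curbside_offset: float = 3.0
    # multiplicative placement jitter: building facades sit at a fairly
    # regular setback, lamppost-mounted curbside samplers at a much more
    # variable kerb distance
    facade_jitter: tuple[float, float] = (0.9, 1.3)
    curbside_jitter: tuple[float, float] = (0.6, 2.0)
    traffic_max_road_distance: float = 50.0  # traffic site must be this close to a busy road
    background_min_road_distance: float = 75.0  # urban background kept off busy roads
    rural_min_road_distance: float = 250.0
    external_margin: float = 1500.0  # how far beyond the border external rural sites sit


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Standardised smooth Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _make_polyline(rng: np.random.Generator, config: RegionConfig) -> np.ndarray:
    """Random gently-bending polyline inside the extent."""
    n_pts = int(rng.integers(2, 5))
    start = rng.uniform([0, 0], [config.width, config.height])
    heading = rng.uniform(0, 2 * np.pi)
    pts = [start]
    for _ in range(n_pts - 1):
        step = rng.uniform(200.0, 600.0)
        heading += rng.normal(0.0, 0.25)
        nxt = pts[-1] + step * np.array([np.cos(heading), np.sin(heading)])
        nxt = np.clip(nxt, [0.0, 0.0], [config.width, config.height])
        pts.append(nxt)
    return np.asarray(pts)


def generate_region(config: RegionConfig | None = None, seed: int = 0) -> Region:
    """Generate roads, land use (fine + coarse) and population for one region.

    Deterministic for a fixed (config, seed). Road generation draws random
    polylines per authority class until the class's target length density is
    reached; flows are lognormal around the class median, and each segment
    carries a count-availability flag drawn with the class's coverage rate.
    """
    config = config or RegionConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    area_km2 = config.width * config.height / 1e6

    segments: list[RoadSegment] = []
    for authority in ("national", "provincial", "municipal"):
        target = config.road_density.get(authority, 0.0) * area_km2 * 1000.0  # metres
        total = 0.0
        i = 0
        while total < target:
            verts = _make_polyline(rng, config)
            z = float(rng.standard_normal())
            # authorities count their busiest roads first: a segment is
            # counted when its flow sits in the class's top coverage
            # quantile, with a 10% chance the flag flips either way
            counted = z > stats.norm.ppf(1.0 - COUNT_COVERAGE[authority])
            if rng.random() < 0.10:
                counted = not counted
            seg = RoadSegment(
                id=f"{authority[:3]}_{i:04d}",
                vertices=verts,
                flow=float(np.exp(np.log(config.flow_median[authority]) + config.flow_sigma * z)),
                heavy_fraction=float(
                    np.clip(rng.normal(config.heavy_fraction_mean[authority], 0.03), 0.0, 1.0)
                ),
                authority=authority,
                has_count_data=bool(counted),
            )
            if seg.length < 50.0:  # degenerate clip against the border
                continue
            segments.append(seg)
            total += seg.length
            i += 1
    roads = RoadNetwork(segments)

    # --- categorical land use: per-category smooth scores, argmax wins.
    ncols = int(round(config.width / config.cell_size))
    nrows = int(round(config.height / config.cell_size))
    shape = (nrows, ncols)
    sigma = 300.0 / config.cell_size  # ~300 m correlation length
    xs = (np.arange(ncols) + 0.5) / ncols
    ys = (nrows - 1 - np.arange(nrows) + 0.5) / nrows
    X, Y = np.meshgrid(xs, ys)
    # urban core near the centre drives residential score; port clings to the
    # western edge; agriculture takes over toward the periphery.
    core = np.exp(-(((X - 0.5) ** 2 + (Y - 0.5) ** 2) / 0.08))
    scores = {
        1: 1.2 * core + 0.8 * _smooth_field(shape, rng, sigma),
        2: 0.4 * _smooth_field(shape, rng, sigma) + 0.3 * core,
        3: 0.9 * np.exp(-X / 0.12) + 0.5 * _smooth_field(shape, rng, sigma) - 0.4,
        4: 0.5 * _smooth_field(shape, rng, sigma) + 0.2,
        5: 1.0 * (1 - core) + 0.6 * _smooth_field(shape, rng, sigma),
        6: 0.7 * _smooth_field(shape, rng, sigma) - 0.1,
    }
    stack = np.stack([scores[c] for c in sorted(scores)])
    cats = np.asarray(sorted(scores))[np.argmax(stack, axis=0)]
    landuse = LandUseGrid((0.0, 0.0), config.cell_size, cats, LANDUSE_CODES)
    landuse_coarse = coarsen_landuse(landuse, config.coarse_factor)

    # --- population follows residential land use.
    pc = config.population_cell
    pcols, prows = int(round(config.width / pc)), int(round(config.height / pc))
    f = int(round(pc / config.cell_size))
    resid = (cats == 1).astype(float)
    resid_block = resid[: prows * f, : pcols * f].reshape(prows, f, pcols, f).mean(axis=(1, 3))
    # dwelling density varies with housing stock, so inhabitants are not a
    # fixed multiple of residential area: modulate by a smooth density field
    density = np.exp(0.6 * _smooth_field((prows, pcols), rng, 500.0 / pc))
    weights = (resid_block + 0.02) * density
    lam = config.population_total * weights / weights.sum()
    population = PopulationGrid((0.0, 0.0), pc, rng.poisson(lam).astype(float))

    return Region(
        roads=roads,
        landuse=landuse,
        landuse_coarse=landuse_coarse,
        population=population,
        extent=(0.0, 0.0, config.width, config.height),
    )


def coarsen_landuse(grid: LandUseGrid, factor: int) -> LandUseGrid:
    """Block-majority aggregation of a categorical raster (coarse dialect)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nrows = grid.nrows // factor
    ncols = grid.ncols // factor
    blocks = grid.categories[: nrows * factor, : ncols * factor].reshape(nrows, factor, ncols, factor)
    codes = np.asarray(sorted(grid.category_names))
    counts = np.stack([(blocks == c).sum(axis=(1, 3)) for c in codes])
    out = codes[np.argmax(counts, axis=0)]
    # top rows of the fine grid map onto top rows of the coarse grid, so the
    # origin stays put only if the extent divides evenly; keep yll aligned.
    yll = grid.origin[1] + (grid.nrows - nrows * factor) * grid.cell_size
    return LandUseGrid((grid.origin[0], yll), grid.cell_size * factor, out, grid.category_names)


class PlacementError(RuntimeError):
    pass


def _busy_segments(network: RoadNetwork, threshold: float = 5000.0) -> list[RoadSegment]:
    return [s for s in network if s.flow >= threshold]


def place_sites(
    region: Region,
    config: CampaignConfig | None = None,
    protocol: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Place monitoring sites of each type; returns a site table (no periods).

    Traffic sites are dropped perpendicular to a randomly chosen busy road at
    the protocol offset (facade 10 m, curbside 3 m by default, with a common
    multiplicative jitter), so for a fixed seed the curbside variant of every
    traffic site is strictly nearer the road centreline than the facade one.
    """
    config = config or CampaignConfig()
    protocol = protocol or config.protocol
    if protocol not in ("facade", "curbside"):
        raise ValueError(f"unknown protocol {protocol!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    xmin, ymin, xmax, ymax = region.extent

    busy = _busy_segments(region.roads)
    if config.site_counts.get("traffic", 0) > 0 and not busy:
        raise PlacementError("traffic sites requested but the region has no busy road")
    geoms = [s.geometry for s in region.roads]
    tree = STRtree(geoms)
    offset = config.facade_offset if protocol == "facade" else config.curbside_offset

    def nearest_road_distance(p: Point) -> float:
        idx = tree.nearest(p)
        return float(geoms[idx].distance(p))

    rows = []

    def traffic_site(i: int) -> dict:
        for _ in range(500):
            seg = busy[int(rng.integers(len(busy)))]
            line = seg.geometry
            t = float(rng.uniform(0.1, 0.9)) * line.length
            base = line.interpolate(t)
            ahead = line.interpolate(min(t + 1.0, line.length))
            tangent = np.array([ahead.x - base.x, ahead.y - base.y])
            norm = np.hypot(*tangent)
            if norm == 0:
                continue
            normal = np.array([-tangent[1], tangent[0]]) / norm
            side = 1.0 if rng.random() < 0.5 else -1.0
            u = float(rng.random())
            fj = config.facade_jitter[0] + u * (config.facade_jitter[1] - config.facade_jitter[0])
            cj = config.curbside_jitter[0] + u * (config.curbside_jitter[1] - config.curbside_jitter[0])
            jitter = fj if protocol == "facade" else cj
            # evaluate the placement at both protocol offsets so the same
            # draws yield a valid site under either protocol
            ok = True
            for off in (config.facade_offset * fj, config.curbside_offset * cj):
                q = Point(base.x + side * off * normal[0], base.y + side * off * normal[1])
                if not (xmin <= q.x <= xmax and ymin <= q.y <= ymax):
                    ok = False
                    break
                if line.distance(q) > nearest_road_distance(q) + 1e-9:
                    ok = False  # another road is nearer; placement ambiguous
                    break
                if line.distance(q) > config.traffic_max_road_distance:
                    ok = False
                    break
            if not ok:
                continue
            p = Point(base.x + side * offset * jitter * normal[0], base.y + side * offset * jitter * normal[1])
            return {"site_id": f"{config.id_prefix}T{i:02d}", "x": p.x, "y": p.y, "site_type": "traffic"}
        raise PlacementError("could not place a traffic site near a busy road")

    def open_site(i: int, prefix: str, site_type: str, min_busy_dist: float) -> dict:
        busy_geoms = [s.geometry for s in busy]
        busy_tree = STRtree(busy_geoms) if busy_geoms else None
        for _ in range(2000):
            p = Point(rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
            if busy_tree is not None:
                d = busy_geoms[busy_tree.nearest(p)].distance(p)
                if d < min_busy_dist:
                    continue
            return {"site_id": f"{config.id_prefix}{prefix}{i:02d}", "x": p.x, "y": p.y, "site_type": site_type}
        raise PlacementError(f"could not place a {site_type} site")

    for i in range(config.site_counts.get("traffic", 0)):
        rows.append(traffic_site(i))
    for i in range(config.site_counts.get("urban_background", 0)):
        rows.append(open_site(i, "U", "urban_background", config.background_min_road_distance))
    for i in range(config.site_counts.get("rural", 0)):
        rows.append(open_site(i, "R", "rural", config.rural_min_road_distance))
    for i in range(config.site_counts.get("rural_external", 0)):
        # ring just outside the study border
        side = int(rng.integers(4))
        m = float(rng.uniform(300.0, config.external_margin))
        along = float(rng.uniform(0.0, 1.0))
        if side == 0:
            x, y = xmin - m, ymin + along * (ymax - ymin)
        elif side == 1:
            x, y = xmax + m, ymin + along * (ymax - ymin)
        elif side == 2:
            x, y = xmin + along * (xmax - xmin), ymin - m
        else:
            x, y = xmin + along * (xmax - xmin), ymax + m
        rows.append({"site_id": f"{config.id_prefix}X{i:02d}", "x": x, "y": y, "site_type": "rural_external"})

    df = pd.DataFrame(rows)
    df["protocol"] = protocol
    return df


def default_background_field(extent: tuple[float, float, float, float]):
    """Smooth regional background: a west-to-east gradient plus a broad bump.

    Emulates a regional pollution gradient across the study area; amplitude
    about 8 ug/m3 across the extent.
    """
    xmin, ymin, xmax, ymax = extent
    w, h = xmax - xmin, ymax - ymin

    def f(x, y):
        u = (np.asarray(x) - xmin) / w
        v = (np.asarray(y) - ymin) / h
        return 8.0 * (1.0 - u) * 0.7 + 4.0 * np.exp(-(((u - 0.45) ** 2 + (v - 0.6) ** 2) / 0.15))

    return f


def _landuse_term(region: Region, x: np.ndarray, y: np.ndarray, truth: GroundTruthParams) -> np.ndarray:
    from .predictors import buffer_fraction  # local import to avoid a cycle

    out = np.zeros(len(x))
    grid = region.landuse
    for i, (xi, yi) in enumerate(zip(x, y)):
        if not grid.contains(xi, yi):
            continue  # outside raster coverage: background + traffic only
        for name, eff in truth.landuse_effects.items():
            if eff == 0.0:
                continue
            try:
                code = grid.code_for(name)
            except KeyError:
                continue
            out[i] += eff * buffer_fraction(grid, (xi, yi), truth.landuse_radius, code)
    return out


def true_components(
    sites: pd.DataFrame, region: Region, truth: GroundTruthParams
) -> pd.DataFrame:
    """Noise-free decomposition of the true process at each site.

    Columns: background (beta0 + field), traffic, landuse, total. The
    traffic kernel sums flow * exp(-d / decay_length) over all segments;
    segments beyond 10 decay lengths contribute < 5e-5 of their flow and are
    skipped.
    """
    bg_field = truth.background_field or default_background_field(region.extent)
    x = sites["x"].to_numpy(float)
    y = sites["y"].to_numpy(float)
    background = truth.beta0 + np.asarray(bg_field(x, y), dtype=float)

    cutoff = 10.0 * truth.decay_length
    traffic = np.zeros(len(sites))
    geoms = [(s.geometry, s.flow) for s in region.roads]
    for i, (xi, yi) in enumerate(zip(x, y)):
        p = Point(xi, yi)
        acc = 0.0
        for g, flow in geoms:
            d = g.distance(p)
            if d <= cutoff:
                acc += flow * np.exp(-d / truth.decay_length)
        traffic[i] = truth.traffic_gain * acc

    landuse = _landuse_term(region, x, y, truth)
    out = sites[["site_id"]].copy()
    out["background"] = background
    out["traffic"] = traffic
    out["landuse"] = landuse
    out["total"] = background + traffic + landuse
    return out


def simulate_concentrations(
    sites: pd.DataFrame,
    region: Region,
    truth: GroundTruthParams | None = None,
    n_periods: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-period concentrations at each site from the true process.

    Returns the site table with ``period_1..period_k`` columns appended;
    values are truncated at zero. Period (seasonal) offsets are drawn once
    per period and shared across sites.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    truth = truth or GroundTruthParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    comp = true_components(sites, region, truth)
    annual = comp["total"].to_numpy()

    period_effects = rng.normal(0.0, truth.period_effect_sd, size=n_periods)
    out = sites.copy()
    for j in range(n_periods):
        noise = rng.normal(0.0, truth.noise_sd, size=len(sites)) if truth.noise_sd > 0 else 0.0
        out[f"period_{j + 1}"] = np.maximum(annual + period_effects[j] + noise, 0.0)
    return out


def apply_missingness(table: pd.DataFrame, rate: float, seed: int = 0) -> pd.DataFrame:
    """Knock out site-period observations independently at the given rate.

    Missingness is completely at random; a draw that would silence every
    period of a site is redrawn for that site, so every site keeps at least
    one observed period.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    cols = period_columns(out)
    for i in out.index:
        for _ in range(1000):
            mask = rng.random(len(cols)) < rate
            if not mask.all():
                break
        out.loc[i, [c for c, m in zip(cols, mask) if m]] = np.nan
    return out
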