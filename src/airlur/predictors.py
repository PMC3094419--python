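"""Site-level GIS predictors: traffic buffers, road distances, land-use and
population buffers.

All geometry is straight-line (no network routing). Distances to roads are
stored log-transformed because traffic-related pollution decays roughly
exponentially with distance to the source; a zero distance is clamped to
``d_min`` (1 m) before the log. When a site has no road of a class anywhere
in the region, the distance is censored at the region diagonal and the flow
set to 0, so the regression design matrix never contains missing cells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .types import Grid, LandUseGrid, PopulationGrid, Region, RoadNetwork

ROAD_CLASSES = ("all", "busy", "main", "freeway")

#: minimal flow assigned to roads without a traffic count, veh/24 hr
MINIMAL_FLOW = 1225.0


@dataclass(frozen=True)
class RoadClassRule:
    """Flow thresholds defining the busy/main road classes (veh/24 hr).

    Thresholds are inclusive (>=), matching how the fitted variables are
    defined; freeways are identified by the managing authority.
    """

    busy_threshold: float = 5000.0
    main_threshold: float = 10000.0
    freeway_authority: str = "national"

    def __post_init__(self) -> None:
        if not self.main_threshold >= self.busy_threshold > 0:
            raise ValueError("need main_threshold >= busy_threshold > 0")


@dataclass
class PredictorConfig:
    """Which buffer radii / cutoffs to extract, and numeric conventions."""

    traffic_buffer_radii: tuple[float, ...] = (100.0, 250.0)
    flow_cutoffs: tuple[float, ...] = (25.0, 50.0, 100.0, 250.0, 500.0)
    landuse_radii: tuple[float, ...] = (300.0, 1000.0, 5000.0)
    population_radii: tuple[float, ...] = (100.0, 300.0, 1000.0, 5000.0)
    road_classes: tuple[str, ...] = ROAD_CLASSES
    d_min: float = 1.0  # metres; clamp before log-transforming distances
    rule: RoadClassRule = field(default_factory=RoadClassRule)


class NoRoadOfClass(Exception):
    """Raised when a network contains no road of the requested class."""


class CoverageError(ValueError):
    """Site falls outside raster coverage."""


def assign_minimal_flow(network: RoadNetwork, minimal: float = MINIMAL_FLOW) -> RoadNetwork:
    """Replace the flow of every no-count-data segment by the minimal flow.

    Returns a copy; segments with count data keep their flow. This is the
    bridge between the true network (which always carries a flow) and what a
    modeller actually observes.
    """
    if minimal < 0:
        raise ValueError("minimal flow must be >= 0")
    out = network.copy()
    for seg in out:
        if not seg.has_count_data:
            seg.flow = minimal
    return out


def classify_road(segment, rule: RoadClassRule | None = None) -> set[str]:
    """Road classes a segment belongs to; main and busy are nested in all."""
    rule = rule or RoadClassRule()
    classes = {"all"}
    if segment.flow >= rule.busy_threshold:
        classes.add("busy")
    if segment.flow >= rule.main_threshold:
        classes.add("main")
    if segment.authority == rule.freeway_authority:
        classes.add("freeway")
    return classes


def _class_segments(network: RoadNetwork, road_class: str, rule: RoadClassRule):
    return [s for s in network if road_class in classify_road(s, rule)]


def nearest_road(
    network: RoadNetwork,
    point: tuple[float, float],
    road_class: str = "all",
    rule: RoadClassRule | None = None,
) -> tuple[float, float, float]:
    """(distance, flow, heavy_flow) of the nearest road of a class.

    Raises :class:`NoRoadOfClass` when the network holds no such road — the
    caller decides how to censor, never a silent zero.
    """
    rule = rule or RoadClassRule()
    segs = _class_segments(network, road_class, rule)
    if not segs:
        raise NoRoadOfClass(road_class)
    p = Point(point)
    best, bd = None, math.inf
    for s in segs:
        d = s.geometry.distance(p)
        if d < bd:
            best, bd = s, d
    return bd, best.flow, best.heavy_flow


def flow_within(
    network: RoadNetwork,
    point: tuple[float, float],
    road_class: str,
    cutoff: float,
    rule: RoadClassRule | None = None,
) -> float:
    """Flow at the nearest road of the class if within ``cutoff`` m, else 0."""
    try:
        d, flow, _ = nearest_road(network, point, road_class, rule)
    except NoRoadOfClass:
        return 0.0
    return flow if d <= cutoff else 0.0


def buffer_traffic(
    network: RoadNetwork, point: tuple[float, float], radius: float, heavy: bool = False
) -> float:
    """Flow-weighted road length inside a circular buffer (veh*m / 24 hr).

    Sum over segments of flow times the length of the segment's intersection
    with the disc; the standard length-weighted buffer-traffic construction.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    x0, y0 = point
    disc = Point(point).buffer(radius, quad_segs=64)
    total = 0.0
    for s in network:
        # cheap bounding-box rejection before the exact intersection
        v = s.vertices
        if (
            v[:, 0].min() > x0 + radius
            or v[:, 0].max() < x0 - radius
            or v[:, 1].min() > y0 + radius
            or v[:, 1].max() < y0 - radius
        ):
            continue
        inter = s.geometry.intersection(disc)
        if not inter.is_empty:
            w = s.heavy_flow if heavy else s.flow
            total += w * inter.length
    return total


def _disc_cells(grid: Grid, point: tuple[float, float], radius: float):
    """(row_idx, col_idx, weight) of cells overlapping the disc.

    Cells whose centre is well inside the disc get weight 1; cells in the
    boundary ring get the fraction of a 4x4 subcell lattice that falls
    inside, a cheap area weighting accurate to ~1% of the disc.
    """
    x0, y0 = point
    cs = grid.cell_size
    xs, ys = grid.cell_centers()
    pad = 0.75 * cs * math.sqrt(2.0)
    ci = np.where(np.abs(xs - x0) <= radius + pad)[0]
    ri = np.where(np.abs(ys - y0) <= radius + pad)[0]
    if len(ci) == 0 or len(ri) == 0:
        return np.empty(0, int), np.empty(0, int), np.empty(0)
    R, C = np.meshgrid(ri, ci, indexing="ij")
    d = np.hypot(xs[C] - x0, ys[R] - y0)
    interior = d <= radius - pad
    ring = (~interior) & (d <= radius + pad)

    rows = [R[interior]]
    cols = [C[interior]]
    weights = [np.ones(int(interior.sum()))]
    if ring.any():
        rr, cc = R[ring], C[ring]
        off = (np.arange(4) + 0.5) / 4.0 - 0.5  # subcell offsets in cell units
        ox, oy = np.meshgrid(off, off)
        sx = xs[cc][:, None] + (ox.ravel() * cs)[None, :]
        sy = ys[rr][:, None] + (oy.ravel() * cs)[None, :]
        frac = np.mean((sx - x0) ** 2 + (sy - y0) ** 2 <= radius**2, axis=1)
        keep = frac > 0
        rows.append(rr[keep])
        cols.append(cc[keep])
        weights.append(frac[keep])
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(weights)


def buffer_fraction(
    grid: LandUseGrid, point: tuple[float, float], radius: float, category: int
) -> float:
    """Share of the category among covered cells whose centre is in the disc.

    Area-weighted cell membership (boundary cells partially counted). Near
    the raster edge the fraction is taken over the covered part of the disc.
    """
    if not grid.contains(*point):
        raise CoverageError(f"point {point} outside raster coverage")
    rows, cols, w = _disc_cells(grid, point, radius)
    if len(rows) == 0 or w.sum() == 0:
        # disc smaller than a cell: fall back to the cell containing the point
        xll, yll = grid.origin
        col = min(int((point[0] - xll) / grid.cell_size), grid.ncols - 1)
        row = min(int((grid.extent[3] - point[1]) / grid.cell_size), grid.nrows - 1)
        return float(grid.categories[row, col] == category)
    return float(np.average(grid.categories[rows, cols] == category, weights=w))


def buffer_population(grid: PopulationGrid, point: tuple[float, float], radius: float) -> float:
    """Inhabitants in the disc; boundary cells enter by their covered share."""
    if not grid.contains(*point):
        raise CoverageError(f"point {point} outside raster coverage")
    rows, cols, w = _disc_cells(grid, point, radius)
    return float((grid.counts[rows, cols] * w).sum())


def landuse_column(category_name: str, radius: float) -> str:
    return f"lu_{category_name}_{int(radius)}"


def build_predictor_table(
    sites: pd.DataFrame,
    network: RoadNetwork,
    landuse: LandUseGrid,
    population: PopulationGrid,
    config: PredictorConfig | None = None,
    region_diagonal: float | None = None,
) -> pd.DataFrame:
    """Compute every configured GIS predictor for every site.

    ``network`` must already carry observed flows (minimal flow assigned).
    Distance columns hold ln(max(d, d_min)); a site with no road of a class
    in the whole region gets the censoring distance (region diagonal) and
    zero flow. Raises :class:`CoverageError` for sites outside the rasters.
    """
    config = config or PredictorConfig()
    rule = config.rule
    if region_diagonal is None:
        xmin, ymin, xmax, ymax = landuse.extent
        region_diagonal = math.hypot(xmax - xmin, ymax - ymin)

    records = []
    for _, site in sites.iterrows():
        p = (float(site["x"]), float(site["y"]))
        if not landuse.contains(*p) or not population.contains(*p):
            raise CoverageError(f"site {site['site_id']} at {p} outside raster coverage")
        rec: dict[str, float] = {"site_id": site["site_id"]}

        for r in config.traffic_buffer_radii:
            rec[f"traf_buf_{int(r)}"] = buffer_traffic(network, p, r, heavy=False)
            rec[f"heavy_buf_{int(r)}"] = buffer_traffic(network, p, r, heavy=True)

        for cls in config.road_classes:
            try:
                d, flow, heavy = nearest_road(network, p, cls, rule)
            except NoRoadOfClass:
                d, flow, heavy = region_diagonal, 0.0, 0.0
            rec[f"logdist_{cls}"] = math.log(max(d, config.d_min))
            rec[f"flow_near_{cls}"] = flow
            rec[f"heavy_near_{cls}"] = heavy
            for c in config.flow_cutoffs:
                rec[f"flow_near_{cls}_within_{int(c)}"] = flow if d <= c else 0.0

        for code, name in sorted(landuse.category_names.items()):
            for r in config.landuse_radii:
                rec[landuse_column(name, r)] = buffer_fraction(landuse, p, r, code)

        for r in config.population_radii:
            rec[f"pop_{int(r)}"] = buffer_population(population, p, r)

        records.append(rec)

    table = pd.DataFrame.from_records(records).set_index("site_id")
    return table


def expected_column_count(config: PredictorConfig, n_categories: int) -> int:
    """Closed-form number of predictor columns for a config."""
    n_traffic_buf = 2 * len(config.traffic_buffer_radii)
    n_class = len(config.road_classes) * (3 + len(config.flow_cutoffs))
    n_landuse = n_categories * len(config.landuse_radii)
    n_pop = len(config.population_radii)
    return n_traffic_buf + n_class + n_landuse + n_pop


def column_dictionary(config: PredictorConfig, landuse: LandUseGrid) -> dict[str, str]:
    """Machine-readable description of every predictor column."""
    d: dict[str, str] = {}
    for r in config.traffic_buffer_radii:
        d[f"traf_buf_{int(r)}"] = f"flow-weighted road length within {int(r)} m (veh*m/24hr)"
        d[f"heavy_buf_{int(r)}"] = f"heavy-duty flow-weighted road length within {int(r)} m"
    for cls in config.road_classes:
        d[f"logdist_{cls}"] = f"ln distance (m) to nearest {cls} road, clamped at {config.d_min} m"
        d[f"flow_near_{cls}"] = f"flow at nearest {cls} road (veh/24hr)"
        d[f"heavy_near_{cls}"] = f"heavy-duty flow at nearest {cls} road"
        for c in config.flow_cutoffs:
            d[f"flow_near_{cls}_within_{int(c)}"] = f"flow at nearest {cls} road if within {int(c)} m else 0"
    for code, name in sorted(landuse.category_names.items()):
        for r in config.landuse_radii:
            d[landuse_column(name, r)] = f"fraction of {name} land use within {int(r)} m"
    for r in config.population_radii:
        d[f"pop_{int(r)}"] = f"inhabitants within {int(r)} m"
    return d


def write_column_dictionary(path, config: PredictorConfig, landuse: LandUseGrid) -> None:
    with open(path, "w") as fh:
        json.dump(column_dictionary(config, landuse), fh, indent=1)
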