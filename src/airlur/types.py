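"""Core domain types: road networks, rasters, monitoring sites, ground truth.

Coordinates are planar metres on a local grid; study extents of a few tens
of kilometres make a planar approximation harmless, so no geodesy anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from shapely.geometry import LineString

AUTHORITIES = ("national", "provincial", "municipal")
SITE_TYPES = ("traffic", "urban_background", "rural", "rural_external")
PROTOCOLS = ("facade", "curbside")

#: site types that enter model fitting; rural_external sites exist only to
#: stabilise the regional-background interpolation near the study border.
MODEL_SITE_TYPES = ("traffic", "urban_background", "rural")


@dataclass
class RoadSegment:
    """A polyline road segment carrying a 24-hour traffic load.

    ``flow`` is the *true* traffic flow used by the concentration simulator.
    Segments with ``has_count_data=False`` emulate roads for which no count
    was supplied by the managing authority; the predictor-extraction side
    must replace their flow by a minimal-flow default before use.
    """

    id: str
    vertices: np.ndarray  # (k, 2) metres, k >= 2
    flow: float  # vehicles / 24 hr
    heavy_fraction: float  # proportion of heavy-duty traffic in [0, 1]
    authority: str  # national | provincial | municipal
    has_count_data: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValueError("segment needs >= 2 planar vertices")
        if self.flow < 0:
            raise ValueError("flow must be >= 0")
        if not 0.0 <= self.heavy_fraction <= 1.0:
            raise ValueError("heavy_fraction must lie in [0, 1]")
        if self.authority not in AUTHORITIES:
            raise ValueError(f"unknown authority {self.authority!r}")

    @property
    def geometry(self) -> LineString:
        return LineString(self.vertices)

    @property
    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    @property
    def heavy_flow(self) -> float:
        return self.flow * self.heavy_fraction


@dataclass
class RoadNetwork:
    segments: list[RoadSegment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def total_length(self) -> float:
        return float(sum(s.length for s in self.segments))

    def by_authority(self, authority: str) -> "RoadNetwork":
        return RoadNetwork([s for s in self.segments if s.authority == authority])

    def copy(self) -> "RoadNetwork":
        return RoadNetwork(
            [
                RoadSegment(
                    s.id, s.vertices.copy(), s.flow, s.heavy_fraction, s.authority, s.has_count_data
                )
                for s in self.segments
            ]
        )


class Grid:
    """Regular raster on a lower-left origin.

    ``values[0, 0]`` is the north-west cell, matching the ESRI ASCII layout;
    row index increases southward, column index eastward.
    """

    def __init__(self, origin: tuple[float, float], cell_size: float, values: np.ndarray):
        if cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.origin = (float(origin[0]), float(origin[1]))  # (xll, yll)
        self.cell_size = float(cell_size)
        self.values = np.asarray(values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        xll, yll = self.origin
        return (xll, yll, xll + self.ncols * self.cell_size, yll + self.nrows * self.cell_size)

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs of columns, ys of rows) — ys ordered north to south like rows."""
        xll, yll = self.origin
        xs = xll + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = yll + (self.nrows - 1 - np.arange(self.nrows) + 0.5) * self.cell_size
        return xs, ys


class LandUseGrid(Grid):
    """Categorical land-use raster; integer codes with a code->label map."""

    def __init__(self, origin, cell_size, categories: np.ndarray, category_names: dict[int, str]):
        super().__init__(origin, cell_size, np.asarray(categories, dtype=np.int32))
        present = set(np.unique(self.values).tolist())
        missing = present - set(category_names)
        if missing:
            raise ValueError(f"cell codes {sorted(missing)} absent from category_names")
        self.category_names = dict(category_names)

    @property
    def categories(self) -> np.ndarray:
        return self.values

    def code_for(self, name: str) -> int:
        for code, label in self.category_names.items():
            if label == name:
                return code
        raise KeyError(name)


class PopulationGrid(Grid):
    """Inhabitant counts per cell."""

    def __init__(self, origin, cell_size, counts: np.ndarray):
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError("population counts must be >= 0")
        super().__init__(origin, cell_size, counts)

    @property
    def counts(self) -> np.ndarray:
        return self.values


@dataclass
class Region:
    """A generated study region: roads plus land-use/population rasters.

    ``landuse`` is the fine-resolution raster (city-campaign dialect);
    ``landuse_coarse`` its block-majority aggregation (large-area dialect,
    standing in for a coarse European land-cover product).
    """

    roads: RoadNetwork
    landuse: LandUseGrid
    landuse_coarse: LandUseGrid
    population: PopulationGrid
    extent: tuple[float, float, float, float]


@dataclass
class GroundTruthParams:
    """Parameters of the synthetic true-concentration process.

    concentration(site, period) =
        beta0 + background_field(x, y)
        + traffic_gain * sum_segments flow * exp(-d / decay_length)
        + sum_cat landuse_effects[cat] * fraction(cat, landuse_radius)
        + period_effect[period] + N(0, noise_sd^2), truncated at 0.
    """

    beta0: float = 10.0  # ug/m3
    background_field: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    traffic_gain: float = 1.0e-3  # ug/m3 per (veh/24 hr) at the kerb
    decay_length: float = 60.0  # metres
    landuse_effects: dict[str, float] = field(
        default_factory=lambda: {
            "residential": 4.0,
            "industry": 5.0,
            "port": 6.0,
            "urban_green": -4.0,
            "agriculture": -3.0,
            "water": -2.0,
        }
    )
    landuse_radius: float = 300.0  # metres; disc over which fractions act
    period_effect_sd: float = 2.0  # ug/m3, one seasonal offset per period
    noise_sd: float = 2.5  # ug/m3 per site-period
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def period_columns(table) -> list[str]:
    """Names of the per-period concentration columns of a site table."""
    return [c for c in table.columns if c.startswith("period_")]


def observed_annual_means(table) -> "pd.Series":  # noqa: F821
    """Mean of the *observed* periods per site (ignores missing cells)."""
    cols = period_columns(table)
    return table[cols].mean(axis=1, skipna=True)
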