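"""Plain-text IO: roads as GeoJSON, rasters as ESRI ASCII grids, sites as CSV.

Both formats are line-oriented text; the GeoJSON follows the LineString
feature convention with flow/heavy_fraction/authority/has_count_data
properties, and ESRI ASCII grids use the usual ncols/nrows/xllcorner/
yllcorner/cellsize header with north-up row order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Grid, LandUseGrid, PopulationGrid, RoadNetwork, RoadSegment, period_columns


# ---------------------------------------------------------------- GeoJSON

def write_roads_geojson(path, network: RoadNetwork) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": seg.vertices.tolist()},
            "properties": {
                "id": seg.id,
                "flow": seg.flow,
                "heavy_fraction": seg.heavy_fraction,
                "authority": seg.authority,
                "has_count_data": seg.has_count_data,
            },
        }
        for seg in network
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_roads_geojson(path) -> RoadNetwork:
    with open(path) as fh:
        data = json.load(fh)
    segments = []
    for feat in data["features"]:
        if feat["geometry"]["type"] != "LineString":
            raise ValueError("road features must be LineStrings")
        p = feat["properties"]
        segments.append(
            RoadSegment(
                id=str(p["id"]),
                vertices=np.asarray(feat["geometry"]["coordinates"], dtype=float),
                flow=float(p["flow"]),
                heavy_fraction=float(p["heavy_fraction"]),
                authority=p["authority"],
                has_count_data=bool(p["has_count_data"]),
            )
        )
    return RoadNetwork(segments)


# ------------------------------------------------------------- ESRI ASCII

def write_ascii_grid(path, grid: Grid, fmt: str = "%g") -> None:
    xll, yll = grid.origin
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {xll}\n")
        fh.write(f"yllcorner {yll}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write("NODATA_value -9999\n")
        np.savetxt(fh, grid.values, fmt=fmt)


def _read_ascii(path):
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    values = np.loadtxt(lines[6:])
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    return header, values


def read_landuse_ascii(path, category_names: dict[int, str]) -> LandUseGrid:
    header, values = _read_ascii(path)
    return LandUseGrid(
        (header["xllcorner"], header["yllcorner"]),
        header["cellsize"],
        values.astype(np.int32),
        category_names,
    )


def read_population_ascii(path) -> PopulationGrid:
    header, values = _read_ascii(path)
    return PopulationGrid((header["xllcorner"], header["yllcorner"]), header["cellsize"], values)


# ------------------------------------------------------------------- CSV

def write_sites_csv(path, sites: pd.DataFrame) -> None:
    """Site table CSV; missing observations become empty cells."""
    sites.to_csv(path, index=False)


def read_sites_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in period_columns(df):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def write_region(outdir, region, category_names: dict[int, str] | None = None) -> None:
    """Write a generated region's layers under a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_roads_geojson(outdir / "roads.geojson", region.roads)
    write_ascii_grid(outdir / "landuse_fine.asc", region.landuse, fmt="%d")
    write_ascii_grid(outdir / "landuse_coarse.asc", region.landuse_coarse, fmt="%d")
    write_ascii_grid(outdir / "population.asc", region.population, fmt="%g")
    names = category_names or region.landuse.category_names
    with open(outdir / "landuse_categories.json", "w") as fh:
        json.dump({str(k): v for k, v in names.items()}, fh, indent=1)
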