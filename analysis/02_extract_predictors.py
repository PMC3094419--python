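"""Extract GIS predictor tables for both campaigns from the written region.

Reads results/region/ (roads, rasters, site tables), assigns the minimal
flow to uncounted roads, computes each campaign's predictor dialect
(coarse land use with 300 m / 1 km / 5 km buffers for the large-area
model; fine land use with 25-500 m buffers for the city model) and writes
predictors_{campaign}.csv plus a column dictionary.
"""

import json
from pathlib import Path

from airlur import gridio
from airlur.pipeline import city_predictor_config, large_area_predictor_config
from airlur.predictors import assign_minimal_flow, build_predictor_table, write_column_dictionary
from airlur.types import MODEL_SITE_TYPES

REG = Path(__file__).resolve().parents[1] / "results" / "region"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    with open(REG / "landuse_categories.json") as fh:
        names = {int(k): v for k, v in json.load(fh).items()}
    roads = assign_minimal_flow(gridio.read_roads_geojson(REG / "roads.geojson"))
    fine = gridio.read_landuse_ascii(REG / "landuse_fine.asc", names)
    coarse = gridio.read_landuse_ascii(REG / "landuse_coarse.asc", names)
    pop = gridio.read_population_ascii(REG / "population.asc")

    for name, grid, config in (
        ("large_area", coarse, large_area_predictor_config()),
        ("city", fine, city_predictor_config()),
    ):
        sites = gridio.read_sites_csv(REG / f"sites_{name}.csv")
        model_sites = sites[sites["site_type"].isin(MODEL_SITE_TYPES)]
        table = build_predictor_table(model_sites, roads, grid, pop, config)
        table.to_csv(OUT / f"predictors_{name}.csv")
        write_column_dictionary(OUT / f"predictors_{name}_columns.json", config, grid)
        print(f"{name}: {table.shape[1]} predictors x {len(table)} sites "
              f"-> predictors_{name}.csv")


if __name__ == "__main__":
    main()
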