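"""Generate the synthetic study region and both monitoring campaigns.

Writes the road network (GeoJSON), fine and coarse land-use rasters and the
population raster (ESRI ASCII), and the two site tables with simulated,
sampler-loss-thinned period concentrations (CSV) under results/region/.
"""

from dataclasses import replace
from pathlib import Path

from airlur import gridio
from airlur.pipeline import StudyConfig, _campaign_seeds
from airlur.synth import apply_missingness, generate_region, place_sites, simulate_concentrations

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "region"


def main() -> None:
    config = StudyConfig()
    region = generate_region(config.region, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    gridio.write_region(OUT, region)
    print(f"region: {len(region.roads)} road segments, "
          f"{region.landuse.nrows}x{region.landuse.ncols} fine land-use cells")

    for tag, campaign, name in ((1, config.large_campaign, "large_area"),
                                (2, config.city_campaign, "city")):
        s_place, s_sim, s_miss, _ = _campaign_seeds(SEED, tag)
        sites = place_sites(region, campaign, campaign.protocol, seed=s_place)
        truth = replace(config.truth, missing_rate=campaign.missing_rate)
        full = simulate_concentrations(sites, region, truth, campaign.n_periods, seed=s_sim)
        observed = apply_missingness(full, campaign.missing_rate, seed=s_miss)
        gridio.write_sites_csv(OUT / f"sites_{name}.csv", observed)
        n_missing = observed.filter(like="period_").isna().to_numpy().mean()
        print(f"{name}: {len(sites)} sites, {campaign.n_periods} periods, "
              f"{100 * n_missing:.1f}% observations lost")


if __name__ == "__main__":
    main()
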