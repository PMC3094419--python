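"""End-to-end study orchestration.

A *study* runs two monitoring campaigns over one synthetic region — a
large-area-style facade campaign (60 sites + 8 external rural, four weekly
periods, ~10.6% sampler loss, coarse land use, regional background entered
a priori) and a city-style curbside campaign (62 sites, thirteen 28-day
periods, ~3.7% loss, fine land use, no a-priori term) — fits one LUR per
campaign, validates each internally (LOOCV) and against the other
campaign, runs the screening dispersion comparator at near-road sites, and
writes every intermediate artefact plus a summary table.

Per-stage seeds are derived from a single master seed by fixed spawn
offsets, so a study is reproducible end to end from one integer.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import car as carmod
from . import gridio
from .background import BACKGROUND_COLUMN, assign_background
from .impute import impute_missing, pool_estimates
from .lur import LURModel, backward_prune, default_plan, fit_coefficients, forward_build, per_iqr_effects, predict
from .predictors import (
    MINIMAL_FLOW,
    PredictorConfig,
    assign_minimal_flow,
    build_predictor_table,
)
from .synth import (
    CampaignConfig,
    RegionConfig,
    apply_missingness,
    generate_region,
    place_sites,
    simulate_concentrations,
)
from .types import MODEL_SITE_TYPES, GroundTruthParams, Region
from .validate import compare_predictions, external_validate, in_sample, loocv, residual_summary

LARGE_RADII = (300.0, 1000.0, 5000.0)
CITY_RADII = (25.0, 50.0, 100.0, 250.0, 500.0)


def large_area_predictor_config() -> PredictorConfig:
    return PredictorConfig(landuse_radii=LARGE_RADII)


def city_predictor_config() -> PredictorConfig:
    return PredictorConfig(landuse_radii=CITY_RADII)


@dataclass
class StudyConfig:
    region: RegionConfig = field(default_factory=RegionConfig)
    truth: GroundTruthParams = field(default_factory=GroundTruthParams)
    large_campaign: CampaignConfig = field(
        default_factory=lambda: CampaignConfig(
            site_counts={"traffic": 18, "urban_background": 34, "rural": 8, "rural_external": 8},
            protocol="facade",
            id_prefix="LA",
            n_periods=4,
            missing_rate=0.106,
        )
    )
    city_campaign: CampaignConfig = field(
        default_factory=lambda: CampaignConfig(
            site_counts={"traffic": 25, "urban_background": 37},
            protocol="curbside",
            id_prefix="AM",
            n_periods=13,
            missing_rate=0.037,
        )
    )
    m_imputations: int = 10
    selection_delta: float = 1.0  # percentage points of adjusted R^2
    background_radius: float = 50_000.0
    idw_power: float = 1.0
    minimal_flow: float = MINIMAL_FLOW
    wind_speed: float = 5.0


@dataclass
class CampaignResult:
    name: str
    sites: pd.DataFrame  # with period columns (post-missingness)
    model_sites: pd.DataFrame  # fitting subset, ordered as the tables
    annual_mean: pd.Series  # consensus across imputations, model sites
    annual_means_by_imputation: pd.DataFrame
    predictors: pd.DataFrame  # own-dialect table, model sites
    model: LURModel
    pooled: pd.DataFrame
    effects: pd.DataFrame
    in_sample: dict
    loocv: dict


def _campaign_seeds(master_seed: int, tag: int) -> list[int]:
    ss = np.random.SeedSequence([int(master_seed), tag])
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]


def run_campaign(
    region: Region,
    config: StudyConfig,
    campaign: CampaignConfig,
    name: str,
    seed_tag: int,
    master_seed: int,
    predictor_config: PredictorConfig,
    coarse_landuse: bool,
    use_background: bool,
    observed_network=None,
) -> CampaignResult:
    """Simulate, impute and fit one campaign; returns everything downstream."""
    s_place, s_sim, s_miss, s_imp = _campaign_seeds(master_seed, seed_tag)
    sites = place_sites(region, campaign, campaign.protocol, seed=s_place)
    truth = replace(config.truth, missing_rate=campaign.missing_rate)
    full = simulate_concentrations(sites, region, truth, campaign.n_periods, seed=s_sim)
    observed = apply_missingness(full, campaign.missing_rate, seed=s_miss)

    imputed = impute_missing(observed, m=config.m_imputations, seed=s_imp)
    ann_by_imp = imputed.annual_means()
    consensus = imputed.consensus_annual_mean()

    model_sites = observed[observed["site_type"].isin(MODEL_SITE_TYPES)].reset_index(drop=True)
    network = observed_network if observed_network is not None else assign_minimal_flow(
        region.roads, config.minimal_flow
    )
    landuse = region.landuse_coarse if coarse_landuse else region.landuse
    table = build_predictor_table(model_sites, network, landuse, region.population, predictor_config)

    a_priori: list[str] = []
    if use_background:
        rural = observed[observed["site_type"].isin(["rural", "rural_external"])]
        rural_means = {sid: float(consensus[sid]) for sid in rural["site_id"]}
        table = assign_background(
            observed, table, rural_means, radius=config.background_radius, power=config.idw_power
        )
        a_priori = [BACKGROUND_COLUMN]

    y = consensus.loc[table.index].to_numpy(float)
    plan = default_plan(table.columns)
    model = forward_build(y, table, plan, a_priori=a_priori, delta=config.selection_delta)
    model = backward_prune(model, y, table, delta=config.selection_delta)

    # Rubin pooling: refit the selected variable set on each imputation's
    # annual means, then combine estimates and SEs across imputations.
    names = ["intercept"] + model.variables
    est, ses = [], []
    for k in range(config.m_imputations):
        yk = ann_by_imp.loc[table.index, f"imp_{k + 1}"].to_numpy(float)
        res = fit_coefficients(yk, table, model.variables)
        est.append(res.params)
        ses.append(res.bse)
    dof = len(y) - len(model.variables) - 1
    pooled = pool_estimates(np.array(est), np.array(ses), n_complete_dof=dof, names=names)

    effects = per_iqr_effects(model, y, table)
    types = model_sites["site_type"].to_numpy()
    rep_in = in_sample(model, y, table, types).to_dict()
    rep_cv = loocv(y, table, model.variables, types).to_dict()

    return CampaignResult(
        name=name,
        sites=observed,
        model_sites=model_sites,
        annual_mean=consensus.loc[table.index],
        annual_means_by_imputation=ann_by_imp,
        predictors=table,
        model=model,
        pooled=pooled,
        effects=effects,
        in_sample=rep_in,
        loocv=rep_cv,
    )


def _cross_table(
    region: Region,
    config: StudyConfig,
    target: CampaignResult,
    predictor_config: PredictorConfig,
    coarse_landuse: bool,
    use_background: bool,
    background_source: CampaignResult | None,
) -> pd.DataFrame:
    """Predictor table of one campaign's sites in the *other* model's dialect."""
    network = assign_minimal_flow(region.roads, config.minimal_flow)
    landuse = region.landuse_coarse if coarse_landuse else region.landuse
    table = build_predictor_table(
        target.model_sites, network, landuse, region.population, predictor_config
    )
    if use_background:
        src = background_source.sites
        rural = src[src["site_type"].isin(["rural", "rural_external"])]
        cons = background_source.annual_means_by_imputation.mean(axis=1)
        rural_means = {sid: float(cons[sid]) for sid in rural["site_id"]}
        sites_all = pd.concat([src, target.model_sites], ignore_index=True)
        table = assign_background(
            sites_all, table, rural_means, radius=config.background_radius, power=config.idw_power
        )
    return table


def run_study(config: StudyConfig | None = None, seed: int = 1, outdir=None) -> dict:
    """Run the full two-campaign study; returns (and optionally writes) results."""
    config = config or StudyConfig()
    region = generate_region(config.region, seed=seed)

    large = run_campaign(
        region, config, config.large_campaign, "large_area", 1, seed,
        large_area_predictor_config(), coarse_landuse=True, use_background=True,
    )
    city = run_campaign(
        region, config, config.city_campaign, "city", 2, seed,
        city_predictor_config(), coarse_landuse=False, use_background=False,
    )

    # cross-campaign validation: each frozen model applied to the other's sites
    city_in_large_dialect = _cross_table(
        region, config, city, large_area_predictor_config(), True, True, large
    )
    large_in_city_dialect = _cross_table(
        region, config, large, city_predictor_config(), False, False, None
    )
    ext_large_on_city = external_validate(
        large.model, city.annual_mean.to_numpy(float), city_in_large_dialect,
        city.model_sites["site_type"].to_numpy(),
    ).to_dict()
    ext_city_on_large = external_validate(
        city.model, large.annual_mean.to_numpy(float), large_in_city_dialect,
        large.model_sites["site_type"].to_numpy(),
    ).to_dict()

    # screening dispersion comparator at near-road sites of both campaigns
    network = assign_minimal_flow(region.roads, config.minimal_flow)
    car_rows = {}
    # the large-area dialect tables carry the IDW background, which serves
    # as the comparator's large-scale background at both campaigns' sites
    for camp, table in ((large, large.predictors), (city, city_in_large_dialect)):
        bg = (
            table[BACKGROUND_COLUMN]
            if BACKGROUND_COLUMN in table.columns
            else pd.Series(float(large.annual_mean.min()), index=table.index)
        )
        inputs = carmod.inputs_from_sites(camp.model_sites, network, bg, config.wind_speed)
        car_rows[camp.name] = carmod.car_predict_batch(inputs)

    comparisons = {}
    for camp, table in (("large_area", large), ("city", city)):
        car_df = car_rows[camp]
        valid = car_df[car_df["valid"]]
        lur_pred = pd.Series(predict(table.model, table.predictors), index=table.predictors.index)
        obs = table.annual_mean
        if len(valid) >= 3:
            comparisons[camp] = {
                "car_vs_lur": compare_predictions(lur_pred.loc[valid.index], valid["total"]),
                "car_vs_observed": compare_predictions(obs.loc[valid.index], valid["total"]),
                "n_valid": int(len(valid)),
            }

    summary_rows = []
    for camp, ext in ((large, ext_large_on_city), (city, ext_city_on_large)):
        summary_rows.append(
            {
                "model": camp.name,
                "n": camp.in_sample["n"],
                "r2_in_sample": camp.model.r2,
                "adj_r2": camp.model.adj_r2,
                "r2_loocv": camp.loocv["r2"],
                "r2_external": ext["r2"],
                "variables": " + ".join(camp.model.variables),
            }
        )
    summary = pd.DataFrame(summary_rows)

    results = {
        "seed": seed,
        "summary": summary,
        "large": large,
        "city": city,
        "external": {"large_on_city": ext_large_on_city, "city_on_large": ext_city_on_large},
        "car": car_rows,
        "car_comparisons": comparisons,
        "region": region,
    }

    if outdir is not None:
        _write_study(Path(outdir), config, results)
    return results


def _jsonable(d):
    if isinstance(d, dict):
        return {k: _jsonable(v) for k, v in d.items()}
    if isinstance(d, (np.floating, np.integer)):
        return d.item()
    return d


def _write_study(outdir: Path, config: StudyConfig, results: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    gridio.write_region(outdir / "region", results["region"])
    for camp in (results["large"], results["city"]):
        d = outdir / camp.name
        d.mkdir(exist_ok=True)
        gridio.write_sites_csv(d / "sites.csv", camp.sites)
        camp.predictors.to_csv(d / "predictors.csv")
        camp.annual_means_by_imputation.to_csv(d / "annual_means_by_imputation.csv")
        camp.effects.to_csv(d / "per_iqr_effects.csv", index=False)
        camp.pooled.to_csv(d / "pooled_coefficients.csv")
        (d / "model.json").write_text(camp.model.to_json())
        with open(d / "validation.json", "w") as fh:
            json.dump(
                _jsonable({"in_sample": camp.in_sample, "loocv": camp.loocv}), fh, indent=1
            )
    with open(outdir / "external_validation.json", "w") as fh:
        json.dump(_jsonable(results["external"]), fh, indent=1)
    with open(outdir / "car_comparisons.json", "w") as fh:
        json.dump(_jsonable(results["car_comparisons"]), fh, indent=1)
    for name, df in results["car"].items():
        df.to_csv(outdir / f"car_{name}.csv")
    results["summary"].to_csv(outdir / "summary.csv", index=False, float_format="%.6f")


# ------------------------------------------------------- focused experiments

def transferability_experiment(config: StudyConfig | None = None, seed: int = 1) -> dict:
    """Internal vs cross-campaign predictive skill of the large-area model.

    Fits the facade-protocol large-area model, scores it by LOOCV, then
    applies the frozen model to the curbside city campaign simulated over
    the same region and truth. Curbside samplers sit nearer the road than
    any fitting site, in the steeper part of the decay kernel and at much
    more variable kerb distances, which is the site-selection mechanism by
    which transfer degrades.
    """
    config = config or StudyConfig()
    region = generate_region(config.region, seed=seed)
    large = run_campaign(
        region, config, config.large_campaign, "large_area", 1, seed,
        large_area_predictor_config(), coarse_landuse=True, use_background=True,
    )

    campaign = config.city_campaign
    s_place, s_sim, s_miss, s_imp = _campaign_seeds(seed, 2)
    sites = place_sites(region, campaign, campaign.protocol, seed=s_place)
    truth = replace(config.truth, missing_rate=campaign.missing_rate)
    full = simulate_concentrations(sites, region, truth, campaign.n_periods, seed=s_sim)
    observed = apply_missingness(full, campaign.missing_rate, seed=s_miss)
    imputed = impute_missing(observed, m=config.m_imputations, seed=s_imp)
    consensus = imputed.consensus_annual_mean()
    model_sites = observed[observed["site_type"].isin(MODEL_SITE_TYPES)].reset_index(drop=True)

    network = assign_minimal_flow(region.roads, config.minimal_flow)
    table = build_predictor_table(
        model_sites, network, region.landuse_coarse, region.population, large_area_predictor_config()
    )
    src = large.sites
    rural = src[src["site_type"].isin(["rural", "rural_external"])]
    cons_large = large.annual_means_by_imputation.mean(axis=1)
    rural_means = {sid: float(cons_large[sid]) for sid in rural["site_id"]}
    table = assign_background(
        pd.concat([src, model_sites], ignore_index=True), table, rural_means,
        radius=config.background_radius, power=config.idw_power,
    )
    ext = external_validate(
        large.model, consensus.loc[table.index].to_numpy(float), table,
        model_sites["site_type"].to_numpy(),
    )
    return {
        "seed": seed,
        "loocv_r2": large.loocv["r2"],
        "in_sample_r2": large.model.r2,
        "external_r2": ext.r2,
        "external_mean_residual": ext.mean_residual,
    }


def parameter_recovery_experiment(
    config: StudyConfig | None = None,
    seed: int = 1,
    traffic_coef: float = 1.2e-5,
    landuse_coef: float = 15.0,
    noise_sd: float = 1.0,
) -> dict:
    """Fit the selection procedure against a known linear truth.

    The response is constructed directly from three predictor columns of a
    generated region — the regional background (coefficient 1), buffer
    traffic within 100 m and the residential fraction within 300 m — plus
    small Gaussian noise, and the full supervised selection is asked to
    find them among all candidate columns. Contributions are balanced so
    every true term clears the 1-point entry rule by construction. Returns
    which families were recovered and the coefficient errors when the
    exact columns were selected.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]).generate_state(1)[0])
    region = generate_region(config.region, seed=seed)
    sites = place_sites(region, config.large_campaign, "facade", seed=seed)
    model_sites = sites[sites["site_type"].isin(MODEL_SITE_TYPES)].reset_index(drop=True)
    network = assign_minimal_flow(region.roads, config.minimal_flow)
    table = build_predictor_table(
        model_sites, network, region.landuse_coarse, region.population, large_area_predictor_config()
    )
    from .synth import true_components

    comp = true_components(sites, region, config.truth)
    bg = dict(zip(sites["site_id"], comp["background"]))
    rural = sites[sites["site_type"].isin(["rural", "rural_external"])]
    table = assign_background(
        sites, table, {sid: bg[sid] for sid in rural["site_id"]},
        radius=config.background_radius, power=config.idw_power,
    )

    truth_cols = {"traf_buf_100": traffic_coef, "lu_residential_300": landuse_coef}
    y = table[BACKGROUND_COLUMN].to_numpy(float).copy()
    for col, coef in truth_cols.items():
        y = y + coef * table[col].to_numpy(float)
    y = y + rng.normal(0.0, noise_sd, len(table))

    model = forward_build(
        y, table, default_plan(table.columns), a_priori=[BACKGROUND_COLUMN],
        delta=config.selection_delta,
    )
    families = {re.sub(r"_\d+$", "", v) for v in model.variables}
    recovered = {"traf_buf", "lu_residential"} <= families
    rel_errors = {}
    for col, coef in truth_cols.items():
        if col in model.coefficients:
            rel_errors[col] = abs(model.coefficients[col] - coef) / abs(coef)
    rel_errors[BACKGROUND_COLUMN] = abs(model.coefficients[BACKGROUND_COLUMN] - 1.0)
    return {
        "seed": seed,
        "variables": model.variables,
        "families_recovered": recovered,
        "exact_columns": all(c in model.variables for c in truth_cols),
        "relative_errors": rel_errors,
    }


def traffic_driven_study_config() -> StudyConfig:
    """Study conditions where municipal arteries carry the urban traffic.

    In Dutch cities most streets people live along are municipally managed;
    this configuration makes the municipal network the dominant local
    source (busy municipal arteries, thinner provincial/national presence),
    which is the regime where withholding municipal counts should hurt.
    """
    region = RegionConfig(
        road_density={"national": 0.05, "provincial": 0.1, "municipal": 2.0},
        flow_median={"national": 30000.0, "provincial": 9000.0, "municipal": 9000.0},
        flow_sigma=0.7,
    )
    return StudyConfig(region=region)


# ------------------------------------------------------- reduced-input runs

def run_reduced_inputs(config: StudyConfig | None = None, seed: int = 1, outdir=None) -> dict:
    """Re-fit both models with degraded inputs and report the R^2 penalty.

    (a) Traffic degradation: municipal-road flows are replaced wholesale by
    the minimal-flow default before predictor extraction (no municipal
    counts available), and the large-area model is re-selected from
    scratch. (b) Land-use degradation: the city model is re-selected with
    the coarse land-use raster (coarse dialect radii) instead of the fine
    one. Deltas are in adjusted-R^2 points against the full-data fits.
    """
    config = config or StudyConfig()
    region = generate_region(config.region, seed=seed)

    full_large = run_campaign(
        region, config, config.large_campaign, "large_area", 1, seed,
        large_area_predictor_config(), coarse_landuse=True, use_background=True,
    )
    full_city = run_campaign(
        region, config, config.city_campaign, "city", 2, seed,
        city_predictor_config(), coarse_landuse=False, use_background=False,
    )

    # (a) municipal flows unknown -> minimal flow everywhere municipal
    degraded = assign_minimal_flow(region.roads, config.minimal_flow)
    for seg in degraded:
        if seg.authority == "municipal":
            seg.flow = config.minimal_flow
    reduced_traffic = run_campaign(
        region, config, config.large_campaign, "large_area_reduced_traffic", 1, seed,
        large_area_predictor_config(), coarse_landuse=True, use_background=True,
        observed_network=degraded,
    )

    # (b) coarse land use for the city model
    reduced_landuse = run_campaign(
        region, config, config.city_campaign, "city_reduced_landuse", 2, seed,
        large_area_predictor_config(), coarse_landuse=True, use_background=False,
    )

    out = {
        "seed": seed,
        "full_large_adj_r2": full_large.model.adj_r2,
        "reduced_traffic_adj_r2": reduced_traffic.model.adj_r2,
        "traffic_penalty": full_large.model.adj_r2 - reduced_traffic.model.adj_r2,
        "full_city_adj_r2": full_city.model.adj_r2,
        "reduced_landuse_adj_r2": reduced_landuse.model.adj_r2,
        "landuse_penalty": full_city.model.adj_r2 - reduced_landuse.model.adj_r2,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "reduced_inputs.json", "w") as fh:
            json.dump(_jsonable(out), fh, indent=1)
    return out
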