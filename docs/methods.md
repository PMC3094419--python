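# Methods

`airlur` implements a complete small-scale NO₂ exposure-modelling workflow —
land-use regression (LUR) with supervised forward selection, multiple
imputation of monitoring data, internal and cross-campaign validation, and a
screening-style dispersion comparator — together with a synthetic-geography
generator that supplies study conditions resembling the Dutch two-campaign
setting it emulates (a ~60-site large-area facade campaign and a ~62-site
city curbside campaign). This note records the models, the defaults and why
they are what they are, and what the synthetic world does and does not show.

## The synthetic world

**Geography.** A region is a planar rectangle (default 8 × 8 km; metres, no
geodesy — at these extents the planar error is negligible). Roads are random
gently-bending polylines generated per managing authority (national /
provincial / municipal) until each class reaches its target length density
(defaults 0.15 / 0.35 / 1.2 km per km², a dense lowland mix). Flows are
lognormal around class medians (30 000 / 9 000 / 2 500 veh/24 hr, σ = 0.5
on the log scale); heavy-duty shares average 15 / 10 / 5 %. Each segment
carries a count-availability flag: authorities count their busiest roads
first, with per-class coverage 94 / 58 / 48 % of segments and a 10 % chance
of the flag flipping either way. Count coverage is deliberately *flow-ranked*
rather than independent — freeway counts come from continuous automated
counters and count programmes target important roads, so an "invisible busy
road" should be rare, not routine.

Land use is a categorical raster (six classes: residential, industry, port,
urban green, agriculture, water) built by taking the arg-max of smooth
per-class score fields (≈300 m correlation length) with an urban core bias;
the fine raster (20 m cells) stands in for a municipal 5 m land-use map and
its 5× block-majority aggregation (100 m cells) for a coarse European
land-cover product. Population follows residential area modulated by a
smooth dwelling-density field (inhabitants are not a fixed multiple of
residential area), drawn as Poisson counts on 100 m cells.

**Ground truth.** The true annual-mean surface is

    c(x, y) = β₀ + B(x, y) + g · Σ_segments flow · exp(−d/λ) + Σ_k e_k · f_k(x, y; 300 m)

with β₀ = 10 µg/m³, a smooth regional background B (west–east gradient plus
a broad bump, ~8 µg/m³ amplitude), an exponential local-traffic kernel with
decay length λ = 60 m and gain g = 10⁻³ µg/m³ per veh/24 hr, and additive
land-use effects e_k (µg/m³ per unit fraction within 300 m; sources
positive, green/agricultural/water negative). Per-period observations add a
shared seasonal offset (SD 2 µg/m³) and site-period noise (SD 2.5 µg/m³),
truncated at zero. The gain is calibrated so simulated site distributions
match the concentration ranges the emulated campaigns report (roughly
10–55 µg/m³ over a large mixed area, up to ~75 µg/m³ at city traffic
sites); λ = 60 m matches the validity scale of the screening dispersion
model. Missingness (sampler loss) is completely at random at the campaign
loss rates (10.6 % / 3.7 %), redrawn per site so nobody loses every period.

**Site placement.** Traffic sites are dropped perpendicular to a randomly
chosen busy road (≥ 5 000 veh/24 hr) at the protocol offset: facade 10 m
from the centreline with a narrow multiplicative jitter (0.9–1.3; building
setbacks are regular), curbside 3 m with a wide jitter (0.6–2.0;
lamppost-mounted samplers sit at variable kerb distances). A placement is
accepted only if the chosen road is the nearest road at both protocol
offsets, so protocol comparisons are clean. Urban-background sites keep
≥ 75 m from busy roads, rural sites ≥ 250 m, and external rural sites sit
in a ring up to 1.5 km outside the border purely to stabilise the
background interpolation.

## GIS predictors

For every site: flow-weighted road length in 100/250 m buffers (total and
heavy-duty; veh·m/24 hr, the standard length-weighted construction — the
aggregation is a package decision since only "traffic flow in buffers" is
conventionally specified); distance to and flow at the nearest road of each
class (all / busy ≥ 5 000 / main ≥ 10 000 / freeway-by-authority;
thresholds inclusive); flow at the nearest road of a class within
25/50/100/250/500 m cutoffs; land-use fractions per category in the
dialect's radii (300 m/1 km/5 km coarse; 25–500 m fine); inhabitants within
100 m–5 km. Distances are stored as ln(max(d, 1 m)) because the local
pollution increment decays roughly exponentially with distance; the clamp
handles sites at distance zero. A site with no road of a class anywhere gets
the distance censored at the region diagonal and flow 0, keeping the design
matrix complete; raster buffers use exact interior cells plus 4×4-subcell
area weights on the boundary ring (a pure cell-centre rule misses the ~2 %
accuracy the oracle tests demand at 300 m radii on 100 m cells). Near the
raster edge, fractions are taken over the covered part of the disc.

## Regional background

The large-area model receives the regional background a priori: for
urban/traffic sites, the inverse-distance-weighted mean (power 1 by default;
the exponent is configurable since only "inverse distance weighted" is
specified) of rural-site annual means within 50 km, with distances clamped
at 1 m; rural sites use their own measured mean. External rural sites
contribute to the interpolation but never to model fitting.

## Imputation and pooling

Missing site-period cells are imputed by chained equations: each period
column is regressed on all other period columns plus site-type indicators
with a Bayesian normal linear model (noninformative prior; posterior draws
of β and σ², posterior-predictive draws for the missing cells),
sweeping all columns 10 times; the chain is repeated m = 10 times
independently. Normal-linear is the conventional default for continuous
chained-equation imputation; predictive-mean matching is deliberately out
of scope. Per-imputation annual means are unweighted period means;
selection runs on the across-imputation mean (the selection-then-pool
ordering is ambiguous in the emulated workflow; selecting once on the
consensus and pooling coefficients per imputation is the reading
implemented). Coefficients refit per imputation are pooled with Rubin's
rules — Q̄ the mean estimate, W the mean squared SE, B the between-imputation
variance, T = W + (1 + 1/m)B — with Barnard–Rubin small-sample degrees of
freedom. Degenerate cases (zero residual variance, rank-deficient designs)
collapse to point estimates via the pseudoinverse rather than failing.

## The LUR builder

Candidates are organised in four ordered groups — traffic, traffic-related
land use (transport/port), population-density-related (population buffers,
residential fractions), other land use — and in *families* (one conceptual
variable across its radii or cutoffs). Selection is supervised forward:
within a group only the best variant per family by univariate R² is
eligible (ties break to the smaller radius — the more local variable);
candidates are offered in decreasing univariate R² and accepted only if the
adjusted R² rises by ≥ 1 *percentage point* (the threshold is interpreted
in points, consistent with reporting R² in percent) and every coefficient
in the augmented model keeps its declared sign (flows and source land uses
positive, log-distances and green/agriculture/water negative; the map is
configurable). Rejected candidates are not re-offered after the model grows
— the strict single-pass reading of adding variables one by one; an
exhaustive-enumeration oracle in the tests covers the alternative orders on
small instances. The a-priori background enters first and is never removed.
Backward pruning then drops the highest-p-value variable whenever its
removal changes adjusted R² by < 1 point, preferring the reduced model.
Effects are reported per interquartile range of the predictor over the
fitting sites; a constant predictor yields a zero effect rather than an
error. Univariate ranking is against the raw response by default, with a
flag to rank against the background-residualised response.

## Dispersion comparator

The screening comparator predicts background + emission × dispersion
factor within 60 m of a road. Emission is flow times a fleet-weighted,
speed-class-dependent emission factor (cars/vans/trucks/buses). The
dispersion factor is quadratic in distance to the road centre up to 30 m
and continues as k/d to the 60 m validity limit, continuous at the break,
strictly decreasing, scaled up in street canyons, multiplied by a tree
factor ≥ 1 and inversely by the regional annual-mean wind speed. The
published tool's calibrated coefficient tables are not public: every factor
here is a configurable placeholder satisfying those qualitative contracts,
so the module supports *structural* comparison (ordering, correlation,
decomposition), not absolute calibration; it works directly in
NO₂-equivalent units with no NOx chemistry. Synthetic inputs derive the
fleet split from the heavy-duty fraction (80/20 trucks/buses; 85/15
cars/vans) and the speed class from the managing authority.

## Validation

All reports give both R² conventions: squared Pearson correlation between
observed and predicted (the scatter-plot sense; primary) and 1 − SSE/SST
against the 1:1 line (`r2_identity`), which additionally punishes bias and
mis-scaling — the two diverge exactly when transfer introduces systematic
error. LOOCV refits coefficients only (not the selection path) on each
n−1 subset; external validation scores a frozen model on the other
campaign's sites with no refitting, using the model's own predictor
dialect extracted at those sites. Residual diagnostics report mean
observed−predicted overall, per site type, and within the top observed
quartile (the hot-spot statistic).

## Problem sizes and numerical choices

The default region (8 × 8 km, ~150 road segments, 400² fine raster) makes a
full two-campaign study run in a few seconds, so the replicate experiments
(20 seeds) stay cheap; these sizes are the package's chosen study scale.
All randomness flows from one master seed through fixed-offset
`SeedSequence` spawns (placement, simulation, missingness, imputation each
get their own stream), so every artefact is bit-reproducible. Buffer
intersections use exact shapely geometry with bounding-box pre-rejection;
discs are polygonised at 64 quadrant segments (length error < 10⁻³
relative).

## What the synthetic results do and do not show

The generator reproduces the *structure* of the emulated study — site
typology and counts, placement protocols, period schedules, sampler-loss
rates, the coarse/fine land-use contrast, count-coverage by authority —
and the directional findings that depend on that structure: withholding
municipal traffic counts costs the traffic-driven large-area model ~15
adjusted-R² points while coarsening land use costs the city model almost
nothing, and the screening comparator tracks both LUR models closely at
near-road sites. It does **not** contain street canyons, congestion or
junction ("hot-spot") excess emissions, meteorology, or measurement-device
differences. Two consequences observed in the replicate experiments are
worth stating plainly. First, because the true process is a smooth function
of exactly the geometry the predictors measure, a facade-fitted model
transfers to curbside sites with mostly a *systematic shift* (which Pearson
R² ignores) rather than added scatter; the external-below-LOOCV ordering
that the real campaigns showed strongly therefore appears here only as a
tendency (≈12/20 replicates), not a regularity. Second, the predictor
families are realistically collinear (population buffers track residential
fractions, nearest-road flow tracks buffer traffic), so the greedy grouped
selection often admits a proxy family in place of the generating one — the
very phenomenon the best-per-family rule exists to manage; exact family
recovery succeeds in ≈12/20 replicates even at noise SD 1 µg/m³, while
coefficient recovery conditional on selecting the right columns is accurate
to a few percent.
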