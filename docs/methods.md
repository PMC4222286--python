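# Methods

`raredx` implements a population-level under-diagnosis analysis for rare
hereditary diseases, developed around the canonical example of hereditary
hemorrhagic telangiectasia (HHT) in a single-payer province served by one
specialist referral centre. The analysis has four legs:

1. **Diagnosed prevalence (D-prevalence).** Crude rates of *diagnosed*
   cases per 5000 adults, by census region and age band. Because the
   disease is autosomal dominant and near-fully penetrant, true prevalence
   should be flat across regions and adult age bands; structure in the
   *diagnosed* rate is therefore evidence of differential ascertainment.
2. **Drive-time access.** A road-network travel-time model that asks
   whether the specialists who see the disease's sentinel symptom
   (recurrent epistaxis → ENT clinics) are physically reachable.
3. **Consultation gap.** Survey summaries of how often patients saw an ENT
   or ER physician for the sentinel symptom *before* diagnosis, and how
   many years earlier.
4. **Benchmark under-diagnosis estimate.** Taking the highest diagnosed
   rate observed in any large city as a proxy for true prevalence
   `r_bench`, the undiagnosed fraction is `1 − r_overall / r_bench`, and
   the implied counts follow from applying `r_bench` to the whole adult
   population.

## The synthetic generative model

The real registry, census and road data are not redistributable, so the
package ships a seeded generator whose outputs have exactly the structure
the analysis assumes. It is first-class, tested code, not a fixture.

**Geography.** A `grid_rows × grid_cols` road lattice with intersections
spaced `cell_length_m` apart (default 12×12 at 5 km — a sparse regional
network on which 30/60/90-minute drive-time contours are non-trivial),
planar coordinates jittered by up to `coord_jitter_frac` (default 0.1) of a
cell, and Gaussian elevations scaled so typical grades are a few percent.
Segments take a road class at fixed proportions (10% primary, 20%
secondary, 70% local) with class speed limits 80/60/40 km/h, and a small
fraction (default 5%) are one-way.

**Population.** `total_population` adults (default 2,000,000) are allocated
by a single multinomial draw over `n_census_units` (default 40) units and
the seven census age decades (20–29 … 80+), so conservation is exact. Unit
weights are Dirichlet(1): units differ in size the way municipalities do.
Decade weights default to a provincial-style pyramid (0.175, 0.175, 0.21,
0.17, 0.12, 0.09, 0.06). Units at or above the median population are
flagged metropolitan; "urban" downstream means metropolitan **and** ≥1000
adults.

**Disease and detection.** True cases per (unit, band) are
`Binomial(population, p)` with `p = true_prevalence_per_5000 / 5000`
(default 1.1/5000, the benchmark-rate proxy for true prevalence). At a
seeded fraction of founder units (default 5%), each true case seeds a
geometric family cluster of configured mean size (default 3, capped by the
band population) — emulating settlement-pattern/founder-effect clustering,
which inflates small-town rates without moving the expected band ratio.
Each true case is then *diagnosed* with probability
`detect_prob_by_ageband[band] × detect_prob_region_multiplier[region]`.
Default detection probabilities are 0.26/1.1 ≈ 0.236 for ages 20–49 and
0.36/1.1 ≈ 0.327 for 50+, so diagnosed band rates come out near 0.26 and
0.36 per 5000 — the published age-band structure — with ratio 0.722.
Diagnosed ages are drawn per decade in proportion to the unit's decade
populations; band boundaries are decade-aligned throughout because census
denominators only exist by decade.

**Survey.** Respondent flags are Bernoulli at the configured marginals
(defaults are the published margins of a 940-respondent cohort), with
consult flags drawn *within* the epistaxis stratum — the questionnaire only
asks consult questions of epistaxis reporters — rescaled so whole-sample
marginals still match. Ages are drawn from **moment-matched truncated
normals**: the underlying (μ, σ) are solved so the zero-truncated
distribution has the configured mean/SD. Without matching, truncation at 0
would shift the ENT interval mean from the configured 13.9 to ≈16.8 years.
For ENT consulters the diagnosis age is consult age + interval, both drawn
directly, so the interval marginal is matched exactly in distribution; the
diagnosis-age marginal for consulters is then *implied* (≈41.7 y) rather
than configured (37.1 y). These published marginals are mutually
inconsistent as a joint model — the mean interval (13.9) exceeds the
difference of mean ages (9.3) — and the generator resolves the conflict in
favour of the interval, the quantity the analysis is about. The ER
interval's configured coefficient of variation (12.6/11.3 > 1) is
infeasible for any zero-truncated normal, whose CV is bounded by 1; there
the generator matches the mean at the configured σ and accepts a smaller
realized SD.

**Determinism.** Every generator draws from its own RNG stream derived
from the master seed plus a fixed operation label, so adding a generator
never perturbs another's output, and identical configs reproduce outputs
field for field. Detection uniforms are consumed in a fixed order given
the true-case set, so raising a detection probability under a common seed
can only add diagnoses (monotonicity, tested).

**What the generator does not emulate.** No pedigree structure beyond
count inflation, no symptom-onset hazards, no referral-pattern geography,
no real postal-code system, no traffic. Passing tests therefore show the
*pipeline* is correct and that parameters put in are recovered; they do
not validate the epidemiological conclusions on real data.

## Prevalence analysis

The exclusion funnel removes deceased/no-address records, then
out-of-area/geocode-failure records, counting each record under its first
matching flag so `included + removals = input` exactly. Rates are
`scale × cases / population` at full precision internally; rounding (2 dp
for rates, integer percents) happens only at reporting. A zero-population
cell with zero cases is *undefined* (not rate 0), keeping inhabited
zero-case cities distinct from uninhabited units; cases in an uninhabited
unit are an inconsistency error.

Rate comparisons use the Pearson chi-square on the 2×2 case/non-case ×
group table (scipy, `df=1`), **without** Yates continuity correction by
default — denominators are whole census populations, where the correction
is immaterial — exposed as an option. The city-size-versus-rate fit is
ordinary least squares (`scipy.stats.linregress`) with an explicit
degenerate-input guard: constant rates return r² = 0; fewer than two
cities or zero population variance raise a fit error.

The benchmark under-diagnosis estimator requires `benchmark ≥ overall`;
the pipeline's default benchmark is the highest defined large-city
(≥50,000 adults) rate, matching the published choice, falling back to the
highest city rate anywhere when no large city exceeds the pooled rate
(the maximum unit rate always bounds the pooled rate from above).

## Drive-time access model

Per-segment time is `3.6 · length_m / speed_kmh · (1 + β · max(0, Δelev /
length))`: uphill travel is penalized linearly in grade (default β = 2, so
a 5% climb adds 10% time) and downhill is free; β = 0 disables elevation.

Turn impedances live on an **edge-expanded** (line-graph) representation:
states are directed segment traversals, and the cost of moving between
consecutive traversals is the arriving segment's travel time plus a
penalty keyed by (maneuver, class of road entered). Maneuvers come from
the signed turn angle between segment bearings: |θ| ≤ 30° straight,
30–150° left, −30 to −150° right; sharper turns are reversals and are
forbidden, which also bans same-segment U-turns. The convention that the
penalty depends on the *entered* road's class (not the exited one) is a
deliberate choice where either reading is defensible. Default penalties
(seconds; straight/right/left): local 5/10/15, secondary 10/20/25, primary
15/25/30 — inside the conventional 5–30 s range, increasing with maneuver
difficulty and road class, fully overridable. One-way segments contribute
a single state.

Service areas are multi-source Dijkstra (networkx) from all clinic anchor
nodes at once; entering the first segment costs its travel time but no
turn penalty; a node's arrival time is the minimum over all entering
traversals, clinic anchors at 0. Arrival times are computed once and
thresholded repeatedly for the 30/60/90-minute profile, so areas nest by
construction. Correctness is defined by oracle equivalence — exhaustive
simple-path enumeration in the state space on small graphs — not by
algorithm identity.

Coverage replaces proprietary GIS buffer polygons with a deterministic
proxy: a census unit is covered iff its centroid lies within
`snap_radius_m` (default 500 m, Euclidean, planar metres) of a reachable
node. Whether commercial buffers cover off-network area is unknowable from
the published account; the snap radius is the exposed, testable
substitute. All coordinates are planar metres; projection from geographic
coordinates is out of scope of this layer.

## Problem sizes and runtime choices

The default test-suite and acceptance runs use deliberately small worlds:
3×3–4×4 lattices for property sweeps (100 seeded fixtures), ≤8-node graphs
for enumeration oracles, 200 replicates of a 500,000-adult, 10-unit world
for the band-ratio recovery (pooled ≈10⁸ person-denominator; delta-method
Monte-Carlo SE of the ratio ≈0.014), and 400 seeds of a two-million-adult
single-unit world for the binomial mean check. These sizes give 3-SE
statistical oracles comfortable resolution while keeping the whole suite
under half a minute.

## Known limitations

- Crude rates only: no spatial smoothing, standardized ratios or Bayesian
  disease mapping, matching the analysis being reproduced.
- The published province-wide coverage figures (92.7/97.8/98.6%) depend on
  the real provincial road network and clinic geocodes and are not
  reproducible here; the access model is validated by oracle equivalence
  and property tests on synthetic networks instead.
- The funnel's published "98.5%" inclusion percentage is not consistent
  with any obvious count ratio; the funnel reports raw counts and leaves
  percentage bases to the caller.
- The overall rate computed from published inputs (5000·556/9,116,380 =
  0.305) rounds to 0.30 while the source rounds to 0.31; the package
  reports the computed value and uses the printed 0.31 only where it is an
  explicit published *input* to the benchmark estimate.
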