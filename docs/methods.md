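# Methods

This note records the models, rules and numerical choices behind
`geobehave`, and what the bundled simulator does and does not emulate.

## Spatial structure

All aggregation uses the standard public base-32 geohash (alternating
longitude/latitude bisection, longitude first). The Earth is a sphere of
radius 6,371,000 m; cell width is measured along the cell's mid-latitude
parallel and height along its meridian, which reproduces the familiar
6-digit ≈ 1.22 km × 610 m and 7-digit ≈ 153 m × 153 m figures on the
equator. Encoding is exact at cell edges: the candidate index from float
arithmetic is corrected against the exact edge coordinates (all geohash
edges are representable doubles), so a point within an ulp of an edge
lands in the same cell an exact bisection would give. Cell membership is
therefore effectively half-open, `[south, north) × [west, east)`.

Point-in-polygon tests (municipality assignment) use even-odd containment
with boundary points counting as inside, via shapely. A cell whose centre
lies on a shared boundary is assigned to the first municipality in the
configuration; cells are never double-counted.

## From fixes to visits

Fixes carry the step increment since the child's previous fix; an
increment always belongs to the interval *ending* at its fix. A visit is a
maximal run of same-cell consecutive fixes; a gap > `max_gap_min` (default
5 min) splits runs, because with sparse or dropped sampling an unsplit run
would fabricate hours-long stays. Runs shorter than `min_visit_min`
(default 1 min) are dropped; a visit's steps exclude the entry fix's
increment. Day summaries cap each inter-fix interval at `max_gap_min`
when accumulating recorded minutes. The residence of a child is the cell
holding the most night-time (00:00–06:00 UTC) recorded minutes, ties going
to the lexicographically smaller code; children without night-time data
are excluded from resident indicators. One timezone is assumed
throughout; the day boundary is UTC.

POI contact: an interval counts toward a POI when both endpoint fixes lie
within `poi_contact_radius_m` (50 m), and a contact is scored when the
accumulated time reaches `poi_dwell_min` (1 min). This proximity detector
is a stand-in: how a "visit to a food-related place" is detected in real
deployments (geofencing, self-report, place polygons) is a data-collection
question outside this package; radius and dwell are configurable.

## Indicators, bases, suppression

Three aggregation bases answer different questions and can legitimately
disagree on the same data: *visits* (mean over stays, repeats counted),
*visitors* (each child pooled first — total steps over total time — then
averaged), and *residents* (behavior anywhere on the map attributed to the
home cell, mitigating the residential fallacy). The worked distinction:
one child with stays (60 steps/60 min) and (10 steps/2 min) yields
mean(60, 300) = 180 steps/h by visits but 70/(62/60) ≈ 67.7 steps/h by
visitors. Percentages use the 1-minute eligibility filter for food-type
indicators and 10 minutes for sports-type ones; resident daily steps use
only days with strictly more than 60 recorded minutes. An aggregate is
published only with strictly more than `suppress_n = 5` contributions on
its own basis ("more than 5" read literally: 5 suppressed, 6 retained).

## Environment characteristics

Per-family cell counts; the grid density (30-m lattice anchored at the
cell's southwest corner, each point counting POIs within 100 m — POIs
outside the cell but within reach of a lattice point count, since the
definition is a radius, not the region); and Food/Sports composites as
sums of the group's family counts. Degree/metre conversion uses 111,320
m/° and the cos(mid-latitude) factor; the sub-metre error at 153-m scale
is irrelevant to the statistics. POI layers are files (CSV or GeoJSON);
live place APIs are out of scope.

## Statistics

Pearson r is computed from the sample (n−1) covariance; p two-sided from
t = r√((n−2)/(1−r²)) with n−2 df; the 95% CI from the Fisher z-transform
with z₀.₉₇₅ = 1.959964. n < 3 and zero-variance inputs raise typed errors,
and the association table flags rather than drops such pairs. Analyses
are stratified by city; no multiple-testing correction by default (raw
per-pair p-values are the dashboard convention), with Benjamini–Hochberg
available as an option. The before/after comparison uses Welch's
unequal-variance t test with Welch–Satterthwaite df (a pooled-variance
Student variant is provided); the municipal support threshold here is one
user per cell — deliberately not the >5 publication rule, since this
analysis feeds an intervention evaluation rather than a public map — and a
visit belongs to a period by its entry timestamp.

## The simulator

The generator emulates the *structure* of a school cohort's mobility, not
any real city: a rectangular city with a grid of municipalities, uniform
schools, and per-category POIs from an inhomogeneous Poisson process (food
categories optionally peaked toward downtown). Children live at uniform
homes, attend the nearest school, and follow home → school → hangout →
home days with straight-line walking; the hangout is drawn within 800 m of
the school and is snapped to a nearby food (or sports) POI with
probability sigmoid(α + β·d), d the local POI count within 150 m — the
coupling the association analysis is asked to recover. Step counts are
Poisson around context rates (home 30, school 250, walking 4800, hangout
600 steps/h) with *per-fix* lognormal dispersion (σ = 0.25). The noise is
deliberately per fix, not per day or per child: a shared day-level
multiplier would correlate all cells a child touches within a period and
make cell-level test statistics anti-conservative, which would be a
property of the noise model rather than of the analysis under test.
Days from `after_start` multiply rates by the child's home municipality's
`activity_shift_after` factor. Fixes are emitted every 60 s while moving
and every 300 s while stationary, each dropped independently with
probability 0.1; step increments accumulate across dropped fixes.

Defaults (200 children, 14 days, 24 schools, 8 municipalities, β = 2) are
the package's reference cohort. What the simulator does *not* model —
road networks, realistic human-mobility laws, device-specific GPS error,
weekends, local-time quirks, heterogeneous POI data quality — bounds what
green tests mean: they show the pipeline recovers what its own generative
model plants, at realistic sampling and dropout, not that any real-city
estimate is unbiased.

## Validation studies

- **Oracles.** `pearson` and `welch_t_test` are checked against direct
  brute-force formula evaluation on 1000 random inputs (|Δ| < 1e-10) and
  against scipy's implementations.
- **Type-I calibration.** 200 replicates of a 4 × 4 km null city, 30
  children × 6 days, with POI-seeking disabled (α → −∞, β = 0) so
  trajectories are generated with zero dependence on the POI layer. The
  behavior is steps/hour per cell; the environment variables are per-cell
  *counts* of four categories at 100 POIs/km². Counts of a homogeneous
  Poisson process over disjoint cells are independent, making the null
  exact; the smoothed 100-m density is intentionally avoided here because
  its spatial autocorrelation, against spatially structured behavior,
  genuinely inflates naive correlation tests (the same caveat applies to
  real data and is inherited from the underlying analysis design, which
  performs no spatial-autocorrelation adjustment). Observed fraction of
  p < .05 must be .05 ± .02.
- **Association recovery.** The reference cohort (200 × 14, β_food = 2):
  %food-visits × food density must be positive with p < .05 over ≥ 200
  school-proximal cells.
- **Shift recovery.** 50 seeds of an 80-child × 14-day cohort with the
  after-period factor 0.5 in one municipality (periods Mar 1–10 vs
  Mar 11–14): detection power > 0.8 in the shifted municipality; other
  municipalities must stay ≤ 0.15 false-positive fraction — slightly above
  the nominal .05 to allow for children whose commutes cross municipal
  borders, a real feature of home-based exposure assignment. Study sizes
  were fixed by a design-time pilot before the acceptance runs.
- **Rule fidelity.** Every published threshold (1-min and 10-min visit
  filters, >60-min day rule, >5 suppression, <1000-m school radius) is
  asserted exactly at its boundary on constructed fixtures.

## Known limitations

Night-time residence assumes the device records overnight; shift workers'
children or phones charged off would defeat it. The association analysis
is correlational by construction — no confounder adjustment, no spatial
autocorrelation modelling — and the before/after comparison is a two-group
test, not an interrupted time series. Geohash cells are not equal-area
across latitudes, so cross-city comparisons of density characteristics
carry a cos(latitude) distortion.
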