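# Methods

## The model

`lucsim` simulates annual land-cover change on a categorical 30 m raster
with six classes — forest, deforested, secondary vegetation, watercourse,
non-forest, urban — of which only the first three are dynamic. Three
transitions are modeled: forest clearing (forest → deforested),
regeneration (deforested → secondary) and secondary cutting
(secondary → deforested); water, non-forest and urban never change state.
The study area is partitioned into *regions* (conservation units,
indigenous lands, a 1-km river buffer, the road-influence zone, isolated
areas, the riparian APP strip and — under the 2012 Forest Code — the
pre-2008-cleared part of the APP), and every quantity below is estimated
and applied per region.

**How much changes** is governed by annual transition rates. Calibration
observes two dated maps Δt years apart, builds the empirical 3-state
transition matrix *P* per region, and annualizes it by the matrix root
*A = P^(1/Δt)* (clipped to non-negative entries and row-renormalized).
The matrix root corrects for cells that chain through two states inside
the window (cleared then regenerated, cut then regrown); when only one
transition is observed it reduces to the scalar compound-survival form
*annual = 1 − (1 − f)^(1/Δt)*, and for Δt = 1 the annual rate is exactly
the observed fraction. Each year's cell demand is `round(rate × sources)`
with the rounding residual carried across years, so long-run totals are
unbiased even when the yearly demand is fractional.

**Where change lands** is governed by weights of evidence. For transition
*T*, evidence layer bin *B* (distances to roads and rivers, altitude,
slope — 10 quantile bins each by default — and categorical soil class),

    W⁺(B) = ln[ P(B | T) / P(B | ¬T) ]

estimated over cells eligible for *T* at the first date. Per cell the
weights are combined additively on the log-odds scale under conditional
independence: `logit(P) = logit(prior) + Σ W⁺`, with the region's annual
rate as the prior. Bins with no eligible cells, and transitions never
observed in a region, get weight 0 ("no evidence") so posteriors stay
finite; conditional-independence testing between layers is deliberately
left to the user.

**Allocation** distributes each region's demand by two stochastic
operators. The *expander* converts cells 8-adjacent to existing patches of
the destination class; the *patcher* seeds new patches with sizes drawn
lognormally around the region's mean patch size (default 1.5 ha, variance
2 ha², ≥ 1 cell) and grows each patch by the neighbor maximizing
`posterior + isometry × converted-neighbor count` (isometry default 0.5,
higher = rounder patches). The expander receives `expander_fraction`
(default 0.5) of the demand. Candidates are restricted to the top
`demand × pruning_factor` (default 10) cells of the posterior surface and
sampled probability-weighted. Within a year the transitions run in a fixed
order — clearing, secondary cutting, regeneration — and a cell that
entered the deforested class during the year is not eligible to regenerate
until the next year; this "no same-year clear-then-regrow" rule is what
closes the carbon ledger exactly. Demand exceeding the eligible candidates
converts everything available and logs the shortfall.

**Road feedback** (optional, off by default in the bundled runs): each year
new segments grow as least-cost paths over a friction surface (roads and
rivers attract; conservation units, indigenous lands and slopes > 20%
repel; infinite cost is impassable) toward targets sampled from the
attractiveness surface, within a per-year length budget. A region whose
network grows by a fraction *g* has its clearing rate scaled by
`1 + β·g` (β default 1), clipped to [0, 1]. The functional form of this
feedback is a documented reconstruction; β is exposed so users can
calibrate it.

## Scenarios

The riparian APP buffer width steps with watercourse width: <30 m → 30 m,
30–50 → 50, 50–200 → 100, 200–600 → 200, >600 m → 500 m. The narrow class
is strictly <30 m and upper class bounds are inclusive (the table labels
pin only the 30 m and 600 m boundaries; the others are a convention,
stated here once). Under the 1965 code the reference is the maximum water
level — buffers measured outward from the floodplain edge, floodplain
included — and under the 2012 code the "regular" (minimum) channel, so
the 1965 APP is a superset wherever floodplains are wider than channels.

* **BASELINE** — historical behavior, six regions, no APP restriction.
* **CODE1965** — clearing and secondary cutting forbidden in the
  (max-water-level) APP region; the forbidden demand *leaks*: it is
  converted to additional secondary-cutting demand in unprotected regions,
  apportioned proportionally to their secondary-vegetation source areas
  (every receiver gets the same rate increment `displaced / Σ secondary`,
  which conserves total year-1 demand exactly). Whether displaced demand
  should flow to all unprotected regions or only spatially adjacent ones
  is an open question; proportional-to-source-area is the documented
  choice.
* **CODE2012** — clearing forbidden in the (regular-channel) APP region;
  the APP2008 sub-region (APP cells already cleared by 2008) keeps its
  secondary-cutting transition, reflecting the minimum restoration
  requirement being adopted. Seven regions.

Region precedence when masks overlap: the APP overrides every region
except conservation units and the road-influence zone; conservation units
override indigenous lands, which override the river buffer; the
road-influence corridor takes precedence over the river buffer (unstated
in the source material; chosen so riverside cells inside the corridor
follow road dynamics). Regeneration is suppressed on urban cells and under
the urban mask in every scenario.

## Carbon accounting

Forest carbon density is 0.485 × total (above- plus below-ground) dry
biomass (Mg/ha). Secondary vegetation accumulates dry biomass linearly at
`secondary_growth` Mg/ha/yr and carries 0.45 carbon fraction, so its
density at age *a* is `0.45 × growth × a`; secondary present in the
initial map starts at the mean age of 5 years, regenerated cells at age 1.
`secondary_growth` has no single defensible literature value at this
grain; it defaults to 10 Mg/ha/yr and every bundled check is written to be
independent of it. Clearing releases a cell's full carbon in the clearing
year (committed, instantaneous — no decay curve); a year's uptake is one
year's accumulation over all cells that remain or enter the secondary
class, and net emission = gross − uptake, netted within the same year.
Because accumulation is linear and regrowth starts at age 1, the ledger is
closed: `stock(t) − stock(t+1) = net(t+1)` to machine precision, which the
tests assert at 10⁻⁶ relative. Linear accumulation is uncapped by default
(horizons are short); an age cap is configurable. Non-CO₂ gases, soil
carbon and wetland methane are out of scope.

## Validation

Spatial validation compares *change* maps (cells whose class changed
between the common start date and the end date), not raw maps. A changed
cell earns credit 1 when a cell with the same (from, to) change exists
within a k×k window in the other map; the directional score is the mean
credit and the reported similarity is the minimum of the two directions,
per window size (defaults 1, 3, 5, 7, 9, 11 — crisp credit within the
window; an exponential distance decay is available behind a flag).
Identical change maps score 1 at every window and the score is
non-decreasing in window size. Quantitative validation reports per-class
`real − simulated` areas (km²) and percentages of the real area, with
percentages flagged undefined for classes absent from the real map.

## The synthetic study area

Because no real rasters ship with the package, a generator builds complete
study areas with known dynamics: spatially autocorrelated fields (smoothed
Gaussian noise) thresholded into classes; four mildly sinuous rivers
spanning four buffer width classes (regular widths 15, 40, 120, 250 m;
max-level widths twice that, floodplain strictly containing the channel);
a highway along the eastern edge with feeder roads, defining a 1.5-km
road-influence corridor; conservation-unit and indigenous-land blocks away
from the roads (≈15% of the area); a small urban seat on the widest
river's bank; and a biomass field (mean 350, sd 50 Mg/ha). Initial
clearing (9% of convertible land, a quarter of it regenerating) is placed
by a susceptibility that decays with distance to roads and rivers, so
calibration has signal. The scales emulate a frontier municipality whose
road corridor and riparian zones are largely distinct regions — the
structural feature the scenario contrast depends on: the riparian APP must
carry real clearing pressure for its protection (and the leakage of its
demand into low-carbon secondary cutting) to matter.

The forward model used to evolve the landscape between dates is the same
family the calibrator assumes — per-region annual rates, cellwise
susceptibility weighting, same within-year transition order — so
parameter-recovery tests are well-posed: calibrating on a generated
(t0, t5) pair recovers region-homogeneous rates within binomial sampling
error (verified unbiased across seeds; the 10% recovery check uses source
pools of several thousand cells so sampling noise sits well inside the
band). What the generator does *not* emulate: real terrain (the DEM is
smoothed noise), river hydraulics, classification error in the input maps,
and policy-driven temporal rate shifts. Passing tests therefore
demonstrate internal consistency of the estimator–simulator loop and the
scenario bookkeeping, not predictive skill on real imagery.

All randomness flows from explicit integer seeds; a run seed fans out to
per-stage child seeds by CRC-32 hashing so stages are independently
reproducible. The bundled analyses use a 200×200 grid (6×6 km at 30 m) and
13 annual iterations, the package's chosen desk-scale problem size; grid
size, rates and every geometry parameter are configuration, not code.

## Known limitations

- Allocation reconstructs patcher/expander mechanics from their observable
  behavior (seed-and-grow with pruning); internal details of the platform
  that popularized them are not public, so patch shapes match in character
  rather than cell-for-cell.
- The leakage apportionment rule and the road-feedback form are documented
  reconstructions with exposed parameters (see above).
- Rates are stationary within a scenario apart from road feedback; no
  policy phase-in or economic dynamics.
- Region-heterogeneous cellwise susceptibility makes multi-year cohorts
  slightly non-Markovian at the region level; the matrix-root annualizer
  assumes region-homogeneous chains and is exact only in that case.
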