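# Methods

## Scope

`livesysmap` implements a two-stage method for mapping chicken and pig
production systems: (1) national (or, for very large heterogeneous
countries, provincial) proportions of extensively raised animals are
modelled as bounded logistic functions of log10 GDP per capita (USD,
purchasing power parity), with uncertainty from a stock-weighted
bootstrap; (2) those proportions disaggregate total livestock rasters
into per-system density maps over rural population, conserving unit
stock totals exactly. A synthetic-data generator provides country tables
and raster worlds with the statistical structure the method assumes, so
every stage is testable without large external downloads.

## Share curves

All curves use `g = log10(GDP per capita)`; GDP ≤ 0 is rejected at
ingestion. The forms are

* chicken extensive: `P_ext = 1 / (1 + exp(4·μ·(λ−g) + 2))`
* pig extensive: `P_ext = α / (1 + exp(4·(μ/α)·(λ−g) + 2))`
* pig intensive: `P_int = 1 − α / (1 + exp(4·(μ/α)·(λ−g) + 2))`

with μ the slope (per log10-USD) of the curve at the point where the
share equals half its range, λ the position parameter, and α ∈ (0, 1]
the asymptotic bound (fixed to 1 for chickens). The chicken intensive
share is the complement `1 − P_ext`; the pig semi-intensive share is the
residual `1 − (P_ext + P_int)`. Where the two fitted pig curves overlap
so that the residual is negative, it is clamped to 0 and `P_ext`,
`P_int` renormalized proportionally, with a warning — the source
formulation is silent on this case, and proportional renormalization is
the least-informative correction that preserves a valid composition.

The printed exponent makes the share *increase* with income when μ > 0;
extensive shares empirically fall with income, so fitted μ is negative
for `P_ext`. No sign constraint is imposed: the direction is an
empirical outcome, not an assumption.

**The two `P_int` forms.** The intensive-pig expression above has range
(1−α, 1): its *floor* at low income is 1−α, which sits oddly with α
being described as the curve's maximum. We implement this form verbatim
as `as_printed` (the default) and offer a `bounded` alternative
`α·σ(u)` with range (0, α), selectable in configuration. The intent of
the original formulation cannot be recovered from its text, so both are
first-class and tested; the choice does not affect any conservation
property downstream.

## Fitting

Curves are fitted by bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method `trf`, ftol = xtol = gtol =
1e-12) on observed national shares. Initial values: λ₀ = median observed
g, μ₀ = −1, α₀ = min(1, max observed share + 0.05). Bounds: α ∈
(1e-6, 1]; μ and λ effectively unconstrained. A fit needs at least as
many distinct GDP values as free parameters plus one (4 for chickens, 5
for pigs); fewer is an error. Non-convergence returns a *flagged*
result rather than raising, so bootstrap replicates can be discarded.
Approximate standard errors come from the Gauss–Newton covariance
`(JᵀJ)⁻¹·s²` at the solution.

## Bootstrap

Defaults: 1,000 replicates, each a 25-unit sample drawn with
replacement with probability proportional to national stock, so large
producers dominate the fitted curves. Further design choices:

* **Degenerate draws.** Under stock-proportional weights a single
  dominant producer (the China-like regime the weighting deliberately
  creates) can yield samples with fewer distinct GDP values than free
  parameters. Such draws cannot pose the regression at all and are
  redrawn (capped at 1,000 attempts per replicate); this is distinct
  from optimizer non-convergence, where the replicate is discarded and
  counted, never refilled. An ensemble with under 50 % converged
  replicates is an error.
* **Percentiles** use linear interpolation between order statistics
  (`np.percentile` default).
* A single seeded `numpy` generator streams through replicates in
  order; identical seed + inputs give bit-identical ensembles.
* Chinese provinces (or any sub-national units) are ordinary units in
  the same species pool; their sampling weights use province stocks.

Per-unit final shares: no observation → ensemble median of the unit's
predicted shares; an observation inside the [1, 99] percentile envelope
of those predictions is retained; outside, it is clipped to the nearer
bound. The rule is idempotent, and its output always lies inside the
envelope spanned by predictions and observation.

## Disaggregation

Per species and unit, with the unit-id raster as the sole authority for
membership:

1. **Suitability mask** — a pixel is suitable iff elevation ≤ 4,750 m,
   slope ≤ 40 %, non-urban, and not permanently snow/ice covered.
   "Higher than" is read strictly, so the threshold values themselves
   remain suitable. Nodata in any input layer renders a pixel
   unsuitable.
2. **Rural population** — the population layer restricted to suitable,
   non-urban pixels.
3. **Harmonization** — the total livestock layer is zeroed outside the
   mask *before* any accounting, then (by default) rescaled per unit so
   its sum matches the reported stock total. Zeroing first keeps the
   invariant that unsuitable pixels are zero in every output while
   preserving conservation against the reported totals; reference total
   layers built with the same mask are unchanged by it. The rescale is
   idempotent; a unit with positive stock but zero gridded sum is an
   error.
4. **Extensive allocation** — pixel value = rural population × (P_ext ·
   total / Σ rural population), so extensive pixel values are exactly
   proportional to rural population and the unit sum equals P_ext ·
   total exactly. Extensive stock with no rural population is an error
   naming the unit.
5. **Commercial by difference with overflow correction** — raw
   commercial = total − extensive. Where negative (allocated backyard
   stock exceeds the mapped total), the total is raised to the
   extensive value, commercial set to 0, and the unit's summed deficit
   D removed pro-rata from remaining commercial pixels (factor
   (S−D)/S, S = raw positive commercial sum). One pass suffices:
   extensive never changes and commercial only shrinks, so no new
   overflow can appear — asserted by a post-check rather than iterated.
   D > S means the unit's shares are inconsistent with its map and is a
   hard error: conservation is the module's contract, and silent
   truncation would hide a data problem.
6. **Pig split** — the commercial layer is divided into semi-intensive
   and intensive in the unit's `p_sint : p_int` ratio, uniformly across
   pixels (semi-intensive production is not assumed to follow rural
   population).

Fractional animals are kept throughout (rounding would break exact
conservation); pixel areas vary with latitude, so head-per-km² export
applies a spherical per-row area correction. All operations are
resolution-agnostic; the default cellsize is 5 arc-min. A per-unit
ledger records stock totals, per-system sums, overflow deficits and
pixel counts; the conservation check requires |Σ systems − total| ≤
1e-6 relative for every unit.

Rasters travel as ESRI ASCII grids (plain text, square cells,
GDAL-compatible, nodata −1), which round-trip values at float32
precision and the geotransform exactly.

## Synthetic data

`WorldSpec` defaults define the test conditions: 60 units, GDP
log-uniform on 500–60,000 USD, log-normal stocks (median ≈ 5 M head,
σ = 2 on the log scale — heavy-tailed so the stock-weighted bootstrap
is exercised in its intended regime), 45 % of units carrying observed
shares, observation noise Gaussian with sd 0.03 clipped to [0, 1], and
one 40 × 40 raster tile per unit so a full world run takes seconds.

True curve parameters are fixed at μ = −1.1, λ = 3.9 for chickens
(extensive share ≈ 0.88 at 1,000 USD, ≈ 0.08 at 10,000 USD — a
transition spanning roughly one income decade) and μ = −0.75 with
α = 0.95 for both pig curves (λ_ext = 4.3, λ_int = 4.4), giving the
wider pig transition in which extensive, semi-intensive and intensive
systems coexist between roughly 1,000 and 30,000 USD.

Per-unit rasters contain: a lognormal rural population background with
one or two dense urban cores (~8 % of pixels); elevation/slope/snow
layers marking ~5 % of pixels unsuitable; and a livestock total built
as true extensive stock (∝ suitable rural population) plus commercial
stock in a few tight Gaussian clusters — commercial production is far
more spatially clustered than backyard production. The constructed
total sums exactly to the unit's stock, and the generating per-pixel
system layers are returned for recovery tests.

What the generator does **not** emulate: real geography and admin
boundaries, peri-urban gradients between city and countryside,
countries whose rural population is not an agricultural population,
spatial autocorrelation of GDP, or the error structure of data-mined
share observations. Passing recovery tests therefore demonstrate
internal consistency of the machinery — that the pipeline recovers the
truth *its own assumptions generate* — not predictive skill on real
national data.

## Problem sizes and determinism

The test suite and the acceptance script use 60-unit worlds (320 × 320
pixels), 200–1,000 bootstrap replicates and 200-seed recovery
experiments; a full acceptance run completes in well under a minute on
one core. Every source of randomness flows from a single configured
seed through `numpy.random.default_rng`; reruns with the same seed are
bit-identical.

## Known limitations

* GDP per capita is the only covariate; countries with similar income
  but different agricultural histories, policies or cultures are not
  distinguished.
* The urban/rural dichotomy ignores peri-urban mixtures, which inflates
  extensive allocations around cities.
* The two pig curves are fitted independently; nothing constrains
  `P_ext + P_int ≤ 1`, which is why the residual clamp exists.
* Observed national shares are treated as exact up to the percentile
  clip; no observation-level error model is fitted.
* The `as_printed` intensive-pig form has a nonzero floor (1−α) at low
  income; users who find that behaviour unphysical should select the
  `bounded` form.
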