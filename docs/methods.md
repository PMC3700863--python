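# Methods

## Scope and data model

The package implements a grid-based, presence-only species distribution
modelling chain with climate-scenario projection. All spatial data live on a
regular WGS84 lon/lat grid (`GridSpec`); arrays are row 0 = southern edge,
cell membership is half-open `[edge, edge + cell_size)` so a point exactly on
an interior edge belongs to the higher-index cell. Rasters are stored as
ESRI ASCII grids — a plain-text format every GIS reads — with NaN for
masked/no-data cells.

## Record cleaning

Four rules, in any order (they commute and are idempotent):

1. records flagged `bbs` (systematic breeding-bird surveys) or `ringing`
   are removed, because those protocols pile records onto a few fixed sites;
2. migratory species keep only dates in the breeding window April 15 –
   July 30, inclusive at both ends;
3. resident species drop dates in December 1 – January 31, inclusive,
   wrapping the year boundary (winter nomadism moves birds off their
   breeding ranges);
4. only species with strictly more than 25 retained records are modelled.

Both date windows are taken inclusive at both endpoints: the printed
calendar endpoints do not specify boundary handling, and symmetric inclusion
is the documented choice here. Duplicate records in one cell are thinned to
a single presence cell by default — the standard treatment for grid-based
presence-only models, where a cell is the observation unit. A
spatial-coverage statistic (fraction of occupied 1°×1° blocks) is reported
as a measurable proxy for "records spread evenly across the region"; it is
never enforced, since any cut-off would be as judgment-based as the visual
screen it replaces.

## Bioclimatic variables

`derive_bioclim` computes the 19 standard BIOCLIM summaries from 12 months
of tmin/tmax/precipitation, in the WorldClim dialect: monthly mean
temperature is (tmin+tmax)/2; BIO4 is 100 × the population standard
deviation of monthly means (not the ANUCLIM CV form); BIO15 is
100 × sd(precip)/(1 + mean(precip)). Quarters are any three consecutive
months with December–January wraparound; ties between equally extreme
quarters resolve to the earliest starting month. Population (not sample)
standard deviations are used throughout. Temperatures are plain °C — the
integer °C×10 storage dialect is deliberately avoided. Two consequences are
tested as invariants: BIO7 = BIO5 − BIO6 cellwise, and adding a constant to
all temperatures shifts the location-type layers by exactly that constant
while leaving spread-type and precipitation layers unchanged. Where the
annual range BIO7 is zero the isothermality BIO3 (= 100·BIO2/BIO7) is set to
0, since a zero annual range forces a zero diurnal range. NaN in any input
month propagates to all 19 layers of that cell.

## Variable selection

Pairwise Pearson correlations are computed across unmasked cells
(pairwise-complete). Variables are then accepted greedily in an explicit
priority order; a candidate is rejected if |r| ≥ 0.75 against any
already-accepted variable (exactly 0.75 counts as correlated). The priority
list is the reproducible stand-in for an expert's "biologically meaningful"
choice; the default puts the eight variables such studies typically retain
first (BIO4, BIO1, BIO15, BIO12, BIO14, BIO8, BIO2, BIO3), then the rest in
ascending order. Zero-variance layers give NaN correlations, treated as
uncorrelated. For migratory species BIO1→BIO10 and BIO14→BIO18 are
substituted after selection (order preserved, duplicates suppressed),
because migrants only experience the warm season on the breeding grounds.
Correlations are computed on the current-period layers only; future layers
are perturbations of the same fields, so pooling would mostly duplicate
cells.

## Maximum-entropy model

Fitting minimizes the convex objective
J(λ) = −(1/m)Σ_presence λ·f(x) + log Σ_background exp(λ·f(x)) + β Σ_j s_j|λ_j|
with per-feature scales s_j = sd over presences / √m. The L1 term is made
smooth by the positive/negative split λ = u − v with u, v ≥ 0, and the
bounded problem is solved with L-BFGS-B (objective-change tolerance 5·10⁻⁵,
iteration cap 1000 — both exposed as settings). Defaults follow MaxEnt
convention: regularization multiplier β = 1.0, up to 10,000 background cells
sampled uniformly without replacement from unmasked cells (presence cells
eligible), 75/25 train/test split with |test| = round(0.25·m).

Features are linear + quadratic + hinge per selected variable, each min-max
scaled to [0,1] on the background; hinge features (10 left-hinges with knots
at evenly spaced background quantiles) activate only with ≥ 15 presences, a
simplified version of auto-feature sample-size rules. Product and threshold
features are omitted: hinges already span piecewise-linear responses and the
desk-scale grids here cannot support interaction terms. A variable constant
on the background keeps only its degenerate linear feature (weight pinned at
0 by the fit). When projecting to another climate, raw values are clamped to
the training min/max before the transforms — the standard guard against
extrapolation, under which all features stay in [0,1].

The mapped output is p = c·q/(1+c·q) with c = exp(H); it is computed in log
space as sigmoid(H + log q) to avoid overflow. Raw and logistic scores are
monotone transforms of each other, so AUC — computed rank-based
(Mann–Whitney) with ties counted 0.5, via `scipy.stats.rankdata` — is
identical under either; thresholds use the logistic scale. AUC uses the
training background as the negative class. Jackknife importance refits with
each variable excluded and alone, reporting training AUC per refit plus the
percent contribution, defined as each variable's share of Σ_j |λ_j·s_j|.

## Thresholding and richness

The 10-percentile training-presence threshold is the smallest training
suitability value v with at least 90% of training presences ≥ v, computed
interpolation-free as sorted_values[m − ceil(0.9·m)] (integer arithmetic).
Binarization uses ≥, so the defining training presences stay predicted
present and training omission is ≤ floor(0.1·m)/m by construction. Richness
is the cellwise integer sum of per-species binary maps; gain/loss maps are
future − current richness.

## Change metrics

Overlap maps are cellwise products; overlap percentage divides surviving
presence cells by current presence cells (unweighted counts, matching the
cell-count definition of overlap). Areas and centroids weight cells by
cos(latitude): at 36–42°N unweighted counts distort areas by ~8% across the
domain. Centroid displacement is the haversine distance on a sphere of
radius 6371 km — projection-free and accurate to well under 0.5% at this
extent. The zonal ellipse is the eigendecomposition of the area-weighted
covariance of presence-cell centers on a km-scaled local tangent plane
(Δlon·cosφ·111.19, Δlat·111.19 km). Turnover is reported both as
consecutive-pair overlaps along the timeline (current→t1→t2→t3) and as
all-timeline persistence (cells present in every period over current cells);
the two differ whenever ranges are not nested, so both are kept. Group
summaries are mean ± population standard deviation, excluding species with
an empty current range (logged).

## Synthetic study system

The generator fabricates what a real study would download or compile.
Monthly climate is a latitudinal mean-temperature gradient (default
−1 °C per degree northward), a seasonal cycle (amplitude 10 °C, July
warmest), a positive diurnal range, and Gaussian-smoothed white-noise
anomaly fields (length scale 3 cells) — the simplest controllable emulation
of spatially autocorrelated climate. Precipitation is a log-normal smooth
field (600 mm/yr at an average cell) with a winter-wet seasonal modulation
whose strength itself varies smoothly in space, as it does between coastal
and continental climates. Future scenarios are additive warming plus a
precipitation factor; the demo uses a stronger scenario (up to +3.6 °C,
−15% precipitation by 2080) and a milder one (+2.7 °C, −9%), three horizons
each.

Species truths are log-linear suitabilities over standardized bioclim
layers, with an optional quadratic term encoding a climatic optimum — the
mechanism that makes a range track its isotherm northward under warming
(a purely linear preference would be invariant to spatially uniform
warming). Occurrences are drawn cell-wise proportional to suitability times
an optional observer-bias kernel around "popular sites", jittered within the
cell, dated uniformly in a configurable window, and flagged casual/bbs/
ringing. The demo study system uses a 20 × 30-cell grid at 0.25°, three
modellable species (two residents, one migrant, 200–300 casual records each
plus survey/ringing admixture) and one deliberately rare species that the
25-record rule must drop.

What the generator does not emulate: topography, land cover, coastlines,
GCM circulation changes (scenario deltas are spatially uniform),
non-stationary observer effort, and taxonomic error. Passing tests
therefore demonstrate correctness of the computational chain and
recoverability of known signal — not that any real species' range will move
as the demo species do.

## Numerical choices and degenerate inputs

Determinism: every stochastic step takes an explicit seed; the pipeline
spawns independent per-species child streams from the master seed
(`numpy.random.SeedSequence`) and records them in the manifest, so reruns
are bit-identical and species do not share randomness. Degenerate cases are
defined rather than left to chance: empty current ranges give NaN metrics
with warnings; a single presence cell gives a zero ellipse; fewer than four
presences put everything in training; zero-variance features keep weight 0;
ties in quarter selection, hinge knots and threshold values resolve
deterministically (earliest month, deduplicated knots, observed values
only). Non-convergence within the iteration cap returns the best iterate
flagged `converged=False` rather than raising.

## Problem sizes

Tests and the demo run on 10×10 to 50×50 grids with tens to hundreds of
presences — sizes at which every brute-force oracle (grid-search
optimization, exhaustive pair counting, subset enumeration) is exact and
fast, and which the parameter-recovery experiment shows are already
sufficient for the fitted distribution to approach the generating truth.
The same code paths scale to continental grids; nothing in the pipeline is
specific to the demo extent.

## Known limitations

The model is a from-scratch maximum-entropy implementation following the
published conventions (feature scaling, regularization form, logistic
output); it is not bit-compatible with any particular MaxEnt release, and
"auto features" is simplified as described above. The percentile-threshold
convention is one of several in circulation; it is documented and tested
here, not claimed to match any specific GIS implementation. Dispersal is
implicitly unlimited: a cell that becomes suitable is counted as occupiable
regardless of distance from the current range.
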