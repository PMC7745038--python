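# Methods

This note documents the models and procedures behind `divgrid`, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not demonstrate about real data.

## Occurrence handling

Records are planar (metres); kilometre-sized analysis cells are
ill-defined in geographic degrees, so analysis never runs on lon/lat.
A helper (`occurrences.lonlat_to_planar`) offers a spherical
equirectangular projection about a user-chosen reference point for
convenience; it is adequate at country scale relative to 12.5–50 km
cells, but for survey-grade work users should supply coordinates in a
proper projected CRS. Grids and occurrence sets carry a free-form
`crs_tag` and refuse to mix.

The pseudo-replication filter keeps one record per (species, x, y, year)
key. Coordinates are compared exactly after parsing; an optional
decimal-places parameter lets users collapse near-duplicates from
mixed-precision sources, but is off by default because any rounding is a
data-cleaning judgement, not part of the method. Records with a missing
year all share a single "unknown" year value in the key — conservative
against over-counting repeat reports of unknown vintage.

## Grids

Cells are half-open squares `[x0+c·s, x0+(c+1)·s) × [y0+r·s, y0+(r+1)·s)`
from the lower-left corner of the country's bounding box (origin and CRS
are configuration: results are reproducible given (CRS, origin, cell
size), and shifting either changes every per-cell number — there is no
canonical grid). Cells with zero clipped area are dropped everywhere;
partially-clipped cells use their clipped area for area accounting but
their full square for point assignment and protected-area intersection.
Sub-grids default to 1 km units; a cell size not divisible by the unit
(12.5 km) requires an explicit divisor (500 m works) rather than a
silent approximation.

## Metrics

Weighted endemism reads "fraction of a species' distribution in the
cell" as occupancy share, `q_ij = 1/(cells occupied by j)`: with
presence-only records there is no defensible within-range area
weighting, and equal weight per occupied cell is the standard form of
range-size-weighted richness. This gives the exact conservation law
`Σ_i E_i = number of recorded species`, which the tests assert to 1e-9.

Threatened proportions use the cell's own species count as denominator;
cells with records but no threatened species score 0 (they are sampled
and unthreatened), while record-free cells are undefined. National-level
metrics are refused — not silently zeroed — for mammals and for the
combined tetrapod set, because no national mammal assessment exists and
a combined denominator would mix assessed and unassessed species.

## Hotspots and congruence

A hotspot definition d selects the top `k = ceil(d/100 · n)` of the n
non-empty cells. `ceil` (rather than round or floor) guarantees a
non-empty selection at d = 2.5% on small grids. Ties at the cut break by
ascending (col, row), which makes selections nested in d and the sweep
deterministic. All metrics in one comparison share a single universe —
cells with at least one record — rather than metric-specific universes.
Congruence is intersection-over-union across *all* compared selections,
in percent; the sweep runs d = 0.5…100 by 0.5. Protected-area overlap
counts a hotspot cell as covered if its square intersects any PA polygon
(boundary contact included: "at least partially covered").

## Corrected correlation (effective sample size)

The Pearson estimate r is never altered; only its inference is. Pairwise
centroid distances (full-square centroids — the lattice geometry, not
clipped shapes) are binned into k = 13 equal-width classes over
(0, d_max] — 13 is the convention of the reference implementation of
this test and is configurable. Per class and variable a Moran-type
estimate ρ̂(h) = mean of z_i z_j / s² (biased s²) fills spatial
correlation matrices R̂_A, R̂_B with unit diagonal; empty classes
contribute 0. Then v̂ = trace(R̂_A R̂_B)/n², M̂ = 1 + 1/v̂, and
t = r√((M̂−2)/(1−r²)) is referred to Student's t with M̂−2 (non-integer)
degrees of freedom. Because estimated correlograms can make the plug-in
trace fall below n, v̂ is floored at 1/n, capping M̂ at n+1 (its exact
value under independence); under iid data this cap binds with
probability ≈ ½ and leaves the test's size at the nominal level (the
suite measures type-I error ≈ 0.05 over 500 replicates at n = 200).
Cells without records are removed before any correlation to avoid
double-zero inflation; n < 5, zero variance, and coincident centroids
are errors, and |r| = 1 is reported as a perfect correlation rather than
a t value.

## Coverage-based rarefaction and extrapolation

Incidence units are 1-km sub-cells **with at least one record of the
focal group**; visited-but-empty units are unknowable from presence-only
data, so T counts occupied units only. The exclusion filter removes a
cell when `S_obs < 6` **or** `T < 6` **or** `U = S_obs` (all species
singletons). The three clauses combine with OR: an AND reading would
keep near-degenerate samples that break the estimators.

Interpolated richness uses the exact hypergeometric form
`S(t) = Σ_j [1 − C(T−Y_j, t)/C(T, t)]`; extrapolation uses the Chao2
unseen-species estimate `Q̂0 = ((T−1)/T)·Q1²/(2Q2)` (the `Q1(Q1−1)/2`
fallback when Q2 = 0 avoids division by zero) in
`S(T+t*) = S_obs + Q̂0[1 − (1 − Q1/(TQ̂0+Q1))^t*]`. Coverage is
`Ĉ(T) = 1 − (Q1/U)·[(T−1)Q1/((T−1)Q1+2Q2)]` at the reference size, the
standard incidence form `1 − Σ_j (Y_j/U)·C(T−Y_j,t)/C(T−1,t)` when
rarefied, and `1 − (Q1/U)·a^{t*+1}` when extrapolated. The rarefied
coverage form is validated in the tests against the closed form at
t = T and against simulations with known detection probabilities.

Standardisation extrapolates every included cell to twice its reference
size; C_max is the minimum and C_5% the 5th percentile (linear
interpolation between order statistics — no percentile method is
canonical, this is numpy's default) of those doubled-size coverages.
Inverting coverage→effort uses integer bisection plus linear
interpolation on the rarefied branch and the closed form on the
extrapolated branch; a cell whose curve cannot reach the target within
its doubled size is capped there and flagged. Non-integer efforts
interpolate richness linearly between adjacent integers, keeping the
inversion and the forward curve consistent.

## Species-accumulation curves and priority classes

SAC sampling units are individual occurrence records (one species
incidence each). Sub-cell units are impossible for resolutions that are
never sub-gridded, and record units make the curve comparable across all
three cell sizes; the incidence machinery above already covers unit-
based analysis where sub-grids exist. The exact curve is the same
hypergeometric form as rarefaction. The "mean slope of the last 10%" is
implemented as the endpoint slope `(S(N) − S(n0))/(N − n0)` with
`n0 = floor(0.9N)` clamped to [1, N−1]: successive finite differences
telescope, so the mean of the per-step slopes over the window equals the
endpoint slope exactly. A curve needs at least `min_records_sac = 2`
points for a slope (configurable upward to emulate stricter software);
cells below that are class High, record-free cells Very High, and the
slope thresholds 0.05 / 0.25 / 1 are right-closed. Well-sampled =
slope ≤ 0.05; the under-sampled area share aggregates clipped areas of
every other cell, including High and Very High.

## Synthetic data generator

The generator's defaults emulate the structure of a national tetrapod
occurrence database: a pool of 664 species (50 amphibians, 68 reptiles,
430 birds, 116 mammals), 69,364 records, a 500 × 350 km rectangular
country (≈ the area of Uruguay), disc-shaped ranges whose equivalent
25-km-cell counts are log-normal (median 15 cells, σ_log = 1.1 — many
restricted-range species, a few widespread ones), effort drawn from
three "coastal city" centres (half-normal kernels, 30 km decay, 80% of
records) over a uniform floor, years uniform on 1950–2019, and threat
labels whose probability follows a decreasing logistic in log range
size (max 0.5, midpoint at 4 cells), with national-level odds doubled
for the groups that have national assessments and mammals left
unassessed. Protected areas are eight random rectangles totalling 1.5%
of the country. Records are generated by sampling a location from the
effort mixture, then a species uniformly among those whose range covers
it — so effort and apparent richness are confounded by construction,
which is exactly the artefact the coverage and completeness machinery
must expose. All draws come from one seeded generator in documented
order, so datasets are byte-reproducible.

What the generator does *not* emulate: real geography and climate
gradients, range shapes other than discs, taxonomic error, temporal
trends in effort, or spatially structured detectability differences
among species. Passing tests therefore demonstrate that the estimators
recover known truths under the stated sampling model, not that any
particular real-world inventory is unbiased.

## Validation problem sizes

The test suite and the acceptance script size their simulations to keep
the whole run fast while leaving Monte-Carlo error well below the
asserted tolerances: endemism conservation on 200 random datasets of
150 records; SAC vs 5,000 random accumulation orders at N = 28;
rarefaction vs 2,000 random subsets at T = 12; test calibration over
500 replicates at n = 200 cells; coverage-standardisation recovery over
50 city-bias replicates of 3,500 records and 60 ubiquitous species on a
200 × 200 km country (uniform true richness, so any richness–effort
correlation among included cells is pure artefact). The full-scale
synthetic analysis in `scripts/acceptance.py` runs at the default
generator size (69,364 records, three grid resolutions).

## Known limitations

- Exact reproduction of any real study's per-cell tables additionally
  requires that study's grid origin and projection, which are rarely
  published; all per-cell numbers here are defined relative to the
  configured (CRS, origin, size).
- The equirectangular projection helper distorts distances away from the
  reference latitude; supply projected coordinates when that matters.
- Incidence-based coverage treats occupied sub-cells as the sampling
  frame; where collecting visits left no records at all, true effort is
  underestimated and coverage overestimated — an intrinsic limit of
  presence-only data, not of the implementation.
- The modified t-test assumes second-order stationary, isotropic spatial
  correlation captured by a binned correlogram; sharp anisotropies or
  nonstationarity are outside its model.
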