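# Methods

## The composite vulnerability index

The index follows the UNDP Human-Development-Index construction: each
raw indicator is min-max normalized across the districts of one state,
Y_i = (X_i − X_min)/(X_max − X_min), and the normalized values are
combined with equal weights. Two points deserve emphasis:

- **Orientation is explicit.** Every `IndicatorSpec` declares whether a
  higher raw value means more or less vulnerability; for
  lower-is-more-vulnerable indicators the series is negated before
  normalization so Y = 1 always marks the most vulnerable district.
  Orientation is never inferred from the data, because a silent sign
  flip inverts every equity conclusion downstream. The default
  five-indicator set (SC/ST share, un-irrigated area, female
  illiteracy, rural share, formation year) is entirely
  higher-is-more-vulnerable: a *later* formation year means a newer
  district with less accumulated infrastructure.
- **Sum, not mean.** The composite is reported as the sum Σ Y_i,
  range [0, k]. On five indicators this is the scale of the published
  VI values (maximum 4.9). The unweighted mean (sum/k) is exposed via
  `compute_index(..., mean=True)`; it is a pure rescaling and cannot
  change a rank, tertile, or correlation.

Min-max normalization makes the index invariant to positive affine
transformations of any raw series (property-tested), but *not* robust
to single-district outliers at the extremes — a known feature of the
HDI recipe, accepted here for comparability.

The index is deliberately *not* validated statistically against
individual-level outcomes: it is built from aggregate district data
only, and health-status indicators are excluded from it by design
because they are downstream of the availability the analysis measures.

## Ranking, tertiles and ties

Districts are sorted on full-precision VI descending, ties broken by
district name ascending — a deterministic, documented total order.
Groups are as equal as possible; when N is not divisible by the group
count, the remainder goes to the most-vulnerable groups first
(conservative toward flagging vulnerability; N = 27 is unaffected).

The packaged published VI column carries one printed decimal and
contains a genuine tie at VI 2.9 spanning the MVD/LVD boundary. The
unrounded values that resolved it were never published, so the
name-based tie-break may swap exactly those two districts relative to
the published grouping; group sizes (9/9/9) and the per-tertile VI
ranges (4.9–3.7, 3.6–2.9, 2.9–0.2) are invariant to the swap and are
what the tests assert.

## Scheme indicators and pooling

All availability/utilization rates use **enrolled persons** as the
denominator, never census population: enrolment is itself a dimension
of access, and holding it equal isolates availability to those who
could use the scheme. Claim indicators count claims *made by hospitals
located in* a district, not claims of its residents — distance and
cost make out-of-district care a materially different service.
Claim-amount rates are reported as INR lakh (100,000) per 100,000
enrolled, the published unit, which numerically equals INR per
enrolled person.

Group rates are pooled (Σ numerator / Σ enrolled), equivalent to an
enrolment-weighted mean of district rates; this keeps the state total
identical to a one-group aggregation and the tertile numerators
additive to the state numerator (both tested).

## Inequality measures

Only the two classical pairwise measures are implemented — rate ratio
and rate difference — comparing MVD and LVD against HVD. Ratios are
computed on full-precision rates and rounded only for display; a zero
reference rate yields a flagged undefined measure rather than
infinity. The published source prints only the ratio columns;
differences are computed and reported but have no printed reference
values. Whole-distribution measures (concentration index, slope index,
Gini) are out of scope.

## Correlation inference

The published analysis reports Pearson coefficients with p-values and
95% intervals but does not state the constructions. Two standard forms
reproduce the printed inference exactly and are therefore adopted:

- p-value: two-sided t-test, t = r√(n−2)/√(1−r²), df = n−2
  (reproduces p = 0.032 at r = 0.414, n = 27);
- CI: Fisher z-transform with the normal critical value,
  tanh(atanh r ± z/√(n−3)) (reproduces the printed lower limit −0.788
  at r = −0.583, n = 27; the printed upper limit −0.260 vs computed
  −0.261 is attributable to the published r itself being rounded).

No multiple-testing correction is applied; significance is per-row at
0.05, matching the published convention. |r| = 1 returns p = 0 and has
no finite-width interval (degenerate-interval error).

## Packaged data and its limits

The packaged district table carries the published one-decimal VI and
per-100k rates; the raw indicator values and unrounded VI were released
only in supplementary files that are not publicly archived. Hence the
full index **cannot be recomputed from raw inputs** for this dataset —
index construction is validated on synthetic and hand-built tables,
and published-data work starts from the printed VI column. Nothing is
imputed to fill that gap. Rounding of the inputs propagates: recomputed
correlations agree with the published coefficients to within about
±0.002 (tested at ±0.02 to be safe against any one-decimal input).

## The synthetic generator

`GeneratorConfig`/`generate_state` emulate the structure the analysis
assumes rather than any particular state's magnitudes:

- Districts occupy the cells of a near-square grid on [−1, 1]²; latent
  vulnerability = `gradient_strength` × distance from the grid centre
  (the "capital") + Gaussian noise (`vuln_noise_sd` = 0.3), mirroring a
  centre-periphery gradient.
- The five raw indicators are monotone noisy linear transforms of the
  standardized latent vulnerability, clipped to their natural supports
  (percentages to [0, 100], formation year to 1948–2012).
- Census population is lognormal (median 950,000, log-sd 0.4);
  enrolment is binomial with logistic coverage
  σ(`enrolment_base` + `coverage_slope`·z); the defaults (0, +0.1) give
  ≈50% coverage, slightly pro-poor, as observed.
- Hospital counts are Poisson with log-rate linear in z per sector,
  baselines 2.2 public / 3.7 private per 100,000 enrolled; the default
  effects `beta_public` = 0 and `beta_private` = −1 reproduce the
  qualitative published pattern (flat public sector, private sector
  avoiding vulnerable districts).
- Claims are Poisson per hospital (650 public / 1,100 private per
  year); amounts multiply claims by a lognormal per-claim cost (means
  INR 3,700 / 6,000, cv ≈ 0.2).

All baseline magnitudes were set once from the observed scale of a
large Indian state. What the generator does **not** model: spatial
autocorrelation beyond the radial gradient, district-size/urbanicity
confounding, measurement error in administrative counts, or any
calibration to exact published magnitudes. Synthetic-recovery tests
therefore demonstrate that the pipeline recovers the signs and
ordering it was pointed at — not that real administrative data meet
the generator's distributional assumptions.

`recovery_experiment` derives one independent stream per replicate
from a root `SeedSequence`, runs the full pipeline per replicate, and
summarizes sign-recovery fractions and mean LVD:HVD ratios (replicates
with a zero HVD rate are excluded from the ratio mean and the default
configuration makes them rare). The standard problem size used in
tests and the acceptance script is 27 districts × 200 replicates,
which runs in well under a minute.

## Geographic export

The choropleth stage joins scores and rates to a GeoJSON
FeatureCollection on the district name (casefolded,
whitespace-normalized), passes geometry through untouched (WGS84
lon-lat assumed, no reprojection), and encodes tertile class as a
property rather than a colour — rendering is a viewer concern. The
real state boundary shapefile is government-licensed and is not
redistributed; mapping is exercised against generated grid-cell
boundaries, for which the join is complete by construction.

## Degenerate inputs and numerical choices

- Constant indicator series → `DegenerateIndicatorError` (no min-max
  scale exists); a constant rate column in the correlation table is
  flagged undefined while other rows proceed.
- Zero enrolled/census denominators → `UndefinedRateError`, never NaN
  or infinity.
- Tables with fewer than three districts, duplicate district names,
  missing columns, or unparsable cells are rejected at read time with
  the offending row/column named; no missing-value imputation exists
  anywhere.
- Pearson r is clipped to [−1, 1] to absorb floating-point overshoot
  on exactly collinear inputs; equality with a loop-level oracle is
  tested to 1e−12.
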