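# Methods

## The composite index

The digital-maturity-in-health index condenses 14 indicators of a country's
digital-health ecosystem into one 0–100 score. Indicators are grouped into
seven subcomponents (infrastructure ×3, workforce ×1, leadership &
governance ×1, strategy & investment ×2, legislation/policy/compliance ×4,
gender diversity ×2, consumer readiness ×1), but the index is the
**unweighted mean of the 14 indicators**, not of the 7 subcomponent scores.
The two aggregation routes coincide only when subcomponents are weighted by
their constituent counts (3, 1, 1, 2, 4, 2, 1); the test suite demonstrates
they disagree under equal subcomponent weights. Subcomponent scores average
whatever constituents are present (with a partial-data flag); the overall
index follows a strict complete-case rule — a country missing any indicator
gets no index and drops out of typing, association and regression.

### Normalization

Indicators arrive on heterogeneous scales (percentages, 0–1 scores, 1–7
survey responses, % of GDP). Two strategies map each onto [0, 100]:

* **min-max** (default): observed minimum → 0, observed maximum → 100,
  linear in between, computed over the loaded analysis set. This is
  reproducible without external reference distributions, but makes scores
  relative to the set being analyzed: adding or removing countries moves
  everyone's index. Whether the original analysis normalized over the
  194-country universe or the 109 complete cases is not stated; we default
  to the loaded set and leave the choice to the caller.
* **fixed-bounds**: linear map of the indicator's declared natural range
  (clipped), for naturally bounded quantities. A fixed-bounds index is
  comparable across analysis sets.

A constant indicator has no min-max image and is reported as an error
naming the indicator rather than silently scored. All 14 default
indicators are oriented higher-is-better; the two gender-gap ratios are
parity ratios where 1 (parity) is the maximum good. No published reversal
rule exists for ratios above parity, so none is applied; a lower-is-better
indicator in a custom catalog is reversed as 100 − scaled.

Missing values are never imputed, and no weighting scheme beyond the
unweighted mean is offered.

## Country types

Complete-case countries are partitioned at the 25th/50th/75th percentiles
of their index values into emerging / transitioner / advanced / leader.
Percentiles use linear interpolation (quantile "type 7"); an index exactly
on a cut point goes to the lower type, matching published interval tables
that are closed and adjacent at one-decimal resolution. The published cut
points (27.9–60.3 / 60.4–69.8 / 69.9–78.3 / 78.4–92.7) ship as the preset
`paper2023` so new data can be typed against the original boundaries; an
index outside a preset's covered range is reported as `out-of-range`,
never clamped. Quartiles are unweighted country counts.

## Association

Because the maturity–performance relationship saturates (performance rises
slowly, then rapidly, then levels off), it is summarized by Spearman's
rank correlation with midranks for ties — invariant under any strictly
monotone transform of either axis. The default 95% CI is the Fisher
z-transform closed form, se = 1/√(n−3), back-transformed with tanh; a
seeded percentile bootstrap (B = 2000 country resamples) is available as a
small-n guard. Pairs with a missing member are dropped and counted. No
curve is fitted and no causal claim is made.

## Spending-efficiency analysis

Each index is regressed on log health expenditure per capita (OLS with
intercept; natural log by default, base-10 available — predictions are
base-invariant). The log transform reduces the right skew of per-capita
spending. Residuals (observed − predicted) measure deviation from the
spending-predicted level; the sign pair (maturity residual, performance
residual) assigns one of four quadrants, with (+, +) meaning
better-than-predicted on both. A residual of exactly zero — measure-zero
in practice — counts as the high side with an explicit boundary flag.
Residual normality is checked with Shapiro–Wilk; a rejection is flagged in
the fit output but triggers no refit, since the diagnostic validates
rather than selects the model. Both regressions run on the same country
set: the intersection of complete cases for both outcomes with positive
expenditure. Expenditure ≤ 0 is an error naming the country. No robust or
weighted variants, no frontier/DEA analysis, no multivariable adjustment.

## Synthetic data generator

The generator is this package's own model of the data-generating process a
cross-country compilation implies; it makes the pipeline testable at full
scale without downloads, and its ground truth (latent capacities, true
regression coefficients, the missingness mask) scores recovery tests.

* **Latent capacity.** One factor *z* per country, normal with sd 0.75
  around a region offset (African −1.10 … European +0.75, ordered like
  observed regional index means). Region sizes follow the WHO member-state
  split (47/35/11/53/21/27 of 194), apportioned deterministically by
  largest remainder.
* **Indicators.** Each is a noisy linear readout of *z* (loading 1.0,
  noise sd 0.6) squashed monotonically onto its natural raw scale.
  At this noise the composite index ranks countries essentially as *z*
  does (Spearman ≥ 0.9).
* **Expenditure.** HE = exp(6.2 + 0.9·z + ε), ε ~ N(0, 0.55): median
  spending near US$ 500 per capita with a realistic 20–8000 range.
* **Performance.** P = 100·logistic(0.9·(z + 0.8)) + N(0, 11), clipped to
  [0, 100] — the saturating link. The noise sd 11 was fixed once by a grid
  search so that the complete-case maturity–performance Spearman
  concentrates near 0.85 (median 0.846 over 60 seeds, all within
  [0.78, 0.90]).
* **Missingness.** By default missing-completely-at-random: each
  subcomponent has a probability that a country misses ≥1 of its
  indicators (legislation 0.397 and leadership 0.010 at the observed
  extremes; the other five set between 0.005 and 0.02 so the closed-form
  missing-any probability 1 − Π(1 − rate) is 0.438, the observed overall
  share). Per-indicator masks are drawn independently at the equivalent
  rate 1 − (1 − R)^{1/m}. An optional `capacity-coupled` mode scales the
  rates by 2·logistic(−z), concentrating missingness in low-capacity
  countries as real compilations do; the mode is recorded in the output
  metadata.

What the generator does **not** emulate: correlated missingness across
subcomponents within a country, indicator-specific loadings and reporting
years, measurement error correlated across indicators from a shared
source, and any resemblance to specific real countries. Passing tests
therefore show the pipeline's arithmetic and statistical behavior under a
plausible generating process, not agreement with any real compilation.

## Numerical conventions

* Percentages and report-table index values round half-up to one decimal
  (banker's rounding would mis-round ties); full precision is kept
  internally and in CSV outputs.
* Missing is serialized as an empty cell (``NA`` also accepted on read)
  and is never conflated with zero.
* CSV outputs carry the run digest in a leading ``#`` comment; a pipeline
  re-run with an identical configuration is byte-identical.
* Spearman values within 1e-12 of ±1 are snapped to exactly ±1; the
  Fisher CI degenerates to a point at that bound.
* OLS is solved by statsmodels; tests cross-check against an independent
  normal-equations solver to 1e-8.

## Problem sizes used in the test suite

Simulation-backed tests run at the analysis's natural scale (194 generated
countries, ~109 complete cases). Seed batteries use 50–100 seeds for
calibration checks, 200 seeds for Monte-Carlo size checks and 500 seeds
for the regression parameter-recovery battery; these sizes give
Monte-Carlo standard errors well inside the asserted margins.

## Known limitations

* A min-max index is relative to its analysis set; cross-study comparisons
  need fixed-bounds normalization or shared reference distributions.
* The complete-case rule discards countries with a single missing
  indicator and is biased when missingness correlates with capacity (the
  generator's coupled mode exists to study exactly that).
* Fisher's CI assumes approximate normality of the z-transformed rank
  correlation; at n ≈ 100 it agrees closely with the bootstrap.
* Quadrant membership near zero residuals is unstable by construction;
  no uncertainty bands are provided.
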