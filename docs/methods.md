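# Methods

This note records the scientific and numerical choices behind
`fireregimes`: what each stage computes, the assumptions it makes, what
the synthetic tropics does and does not emulate, and where the design
was genuinely open.

## Fire characteristics

A cell's fire regime is summarised by 12 numbers: monthly and yearly
mean and coefficient of variation (CV) of burned area (km²), fire count,
and mean fire size (km²), plus the fire-season length (mean number of
months per year with any burned area; reported alongside but not part of
the clustering vector).

* Monthly statistics are computed over the 12-value climatology (mean of
  each calendar month across years) and so measure the shape of the
  seasonal cycle.  Yearly statistics are computed over per-year annual
  aggregates — burned area and count summed, annual fire size = annual
  burned area ÷ annual count (0 in fire-free years) — and measure
  interannual variability.  The computation order (climatology first
  vs CV of raw months) matters and is fixed by this interpretation.
* CV uses the sample (n−1) standard deviation; a zero mean defines
  CV = 0.  This keeps almost-fire-free cells finite rather than NaN, at
  the cost of making the zero-fire corner of characteristic space
  artificially placid — those cells are excluded as NLSF anyway.
* Months with zero fires contribute a mean fire size of 0 (not missing)
  to the climatology, keeping the 12-vector complete for clustering; a
  fire-month-only variant is available via the underlying table if
  needed.
* Normalisation is min–max to [0, 1], fitted on the *burned cells of a
  reference domain* (the focal region by default; the whole domain via
  configuration).  The fitted parameters are reused to transform
  projection data, and values outside the reference range deliberately
  map outside [0, 1] — MESS needs the un-clipped geometry.

NLSF ("no landscape-scale fire") cells are those with zero total burned
area over the span.  The detection floor is enforced at event level in
the generator (fires < 0.21 km² ≈ 21 ha are dropped before
aggregation), so a cell whose only fires are sub-floor is genuinely
NLSF, mirroring how a 500 m burned-area product is blind to small fires.

## Regime definition

Agglomerative clustering with complete linkage (each merge scored by the
maximum pairwise dissimilarity) on Euclidean distances between
normalised characteristic vectors, cut to exactly K clusters (default
K = 5).  The distance metric is a design choice — the linkage is
standard for this problem but the metric is not dictated — and Euclidean
on unit-range variables is the natural default.  A Ward variant is
available behind a flag for comparison.  Labels are renumbered so they
ascend with cluster-mean annual burned area: regime 1 is always the
lowest-fire cluster and regime K the highest, making labels comparable
across runs and row orders.

Cut-height diagnostics report, for each candidate K, the merge height at
which K clusters collapse to K−1 relative to the tree height, with a
flag at the 50% level.  One geometric caveat discovered during
development: when regimes lie along a single fire-activity gradient
(near-collinear cluster centroids), the K-th cut height is bounded near
1/(K−1) of the tree height, so the 50% flag can only fire for more
simplex-like geometries.  On gradient-structured data the informative
signal is the *largest relative gap* between successive cut heights,
which lands at the planted K in the synthetic experiments.  K selection
remains a manual, diagnosed choice; nothing selects K automatically.

## Tropical projection (MESS)

For each regime, each of the 12 variables is scored against the regime's
focal reference sample with the standard similarity formula (percentage
of reference values strictly below the probe; ties count as not-below,
switchable).  The cell's similarity is the minimum over variables;
positive means inside the reference range on every variable; 100 is
attained at the per-variable median.  A degenerate variable (reference
max = min) scores 100 at the constant and a −10⁶ sentinel elsewhere.

Classification: NLSF cells keep label 0; burned cells non-positive for
every regime are dissimilar (−1); the rest take the regime of maximum
similarity — the assignment rule for overlapping surfaces is not
dictated by the method and "maximum similarity" is this package's
documented choice.  Cells whose similarity exceeds 24 for exactly one
regime form the mutually exclusive subset; both thresholds (0 and 24)
are configuration constants, not computed quantities.

The formula is a step-percentile construction, so the score is constant
between consecutive reference values and jumps by up to 200/n at each —
it is continuous only in the large-reference limit.  Practically this
makes MESS a *large-sample* instrument: with n reference cells per
regime, a same-population probe falls outside the min–max range of one
variable with probability ≈ 2/(n+1), and across 12 (correlated)
variables the false-dissimilar rate is material below a few hundred
reference cells.  The projection experiment therefore uses a 160 × 160
lattice with a 45% focal region (~1600 reference cells per regime) —
chosen as the scale at which the instrument, not the sample, limits the
answer.

## Niche overlap

Three reduced environments — fire (12 characteristics), vegetation
(NDVI mean/annual CV/monthly CV, tree cover, tree loss), climate
(temperature mean and seasonality CV, annual precipitation and
seasonality CV) — are each standardised and reduced to two principal
axes, fit on the pooled tropics so regional score clouds share one
coordinate system.  Overlap between two regions' clouds for one regime
is Schoener's D over a shared R × R discretisation.  The default is a
*binary* occupancy weighting (every occupied bin counts once), with the
classical density weighting as a mode; both are reported.  Binary D is
resolution-dependent — at fine R two finite samples of the same niche
occupy different bins, driving D toward 0 — so the default R = 100 maps
are best read comparatively, and coarse grids (R ≈ 10) are appropriate
when an absolute "same niche" judgement is wanted.  D on identical grids
is exactly 1, on disjoint grids exactly 0, and refining R cannot raise
binary D for disjoint clouds.

## Trends

Regime-wide: annual burned area summed over a regime × region cell set,
OLS on the year index, two-sided t test on the slope at α = 0.05 (0.01
also reported downstream), relative change = 100 · slope · (n−1) ÷
fitted first-year value.  The fitted-endpoint denominator is a
documented choice; a mean-relative variant would differ only by the
series' curvature.

Pixel-wise rainfall-decoupled: annual burned area per cell regressed on
{year index, antecedent 6-month precipitation sum, antecedent 24-month
sum}.  The fire year is anchored at the cell's climatological peak
burning month so the antecedent windows precede the burning season;
sums cover the 6 and 24 months strictly before the anchor, which is why
a 24-month precipitation lead is required before the first analysis
year.  The year coefficient is the anthropogenic (rainfall-decoupled)
component and its t-value is the map statistic.  Constant precipitation
features are dropped with a warning (reducing to plain OLS).  No
multiple-testing correction is applied across pixels; the per-pixel
flags are descriptive, and their calibration is verified by simulation
(type-I error at nominal α on purely precipitation-driven data).
Annual response with antecedent-sum covariates is the default cadence;
the regression is correctly specified for the synthetic generator's
linear coupling by construction, which is what makes the calibration
test meaningful.

## Degradation

Vegetation classes come from three NDVI statistics normalised by the
domain-wide maximum mean NDVI (the product-agnostic reading of
"normalised"; min–max is switchable): forest = normalised mean > 0.80
and annual CV < 0.08; grassy = 0.06 ≤ normalised mean < 0.80 and
monthly CV > 0.08; everything else "other".  The 6% floor excludes
barren surfaces from the grassy class.  The rules are checked first
forest, then grassy, so every cell lands in exactly one class.  A 5-day
(configurable odd-window) rolling median is provided for dense NDVI
scene series; the monthly synthetic NDVI does not need it.

Tree-loss fraction of a cell set = Σ loss ÷ Σ baseline cover (undefined
on zero cover, reported missing).  Anomaly ratio = stratum fraction ÷
all-tropics fraction, so the all-tropics row is exactly 1 by
construction.  Population ratios use area-weighted stratum means (plain
means on the uniform lattice).  Empty strata appear as missing rows
rather than being dropped.

## The synthetic tropics

The generator emulates the *inputs* of the comparative analysis, not any
satellite instrument: a three-region lattice (focal / continental /
other, assigned in contiguous blocks so regional statistics carry
spatial structure), K regime archetypes plus an NLSF fraction, monthly
precipitation with a seasonal cycle and interannual noise, NDVI cycles
separated by planted vegetation class, population density, and tree
cover/loss with planted anomaly ratios.  A truth record (labels, trends,
classes, anomalies, seed) makes every dataset exactly regenerable and
auditable.

Key generative choices, with reasons:

* **Event-level fire.**  Each cell-month's burned-area target is split
  into individual fires (lognormal sizes around the archetype's mean,
  rescaled to the exact monthly target; event count by unbiased
  stochastic rounding of target ÷ mean size).  Events below 0.21 km²
  are dropped before aggregation, so the detection floor acts exactly
  where it does in real products, and burned area = count × mean size
  holds identically.
* **Default archetypes.**  Five regimes on the low-variable →
  high-stable gradient: annual burned-area totals 4, 12, 36, 108,
  216 km² per 100 km² cell (≥ 3× spacing), year CVs 0.30 → 0.05,
  season widths 3 → 11 months, mean fire sizes 0.6–9 km² with the
  largest fires in the high-stable regime and a large-fire/low-count
  boundary regime (regime 2) breaking the strict size ladder.  The
  spacing follows the design conditions under which regime recovery is
  the instrument's to lose: with these defaults the planted silhouette
  exceeds 0.5 and complete linkage recovers the labels (ARI 1.0 in most
  seeds, ≥ 0.9 typically).
* **Regionally coherent fire years.**  Year-to-year multipliers are
  drawn per regime-year and shared across a regime's cells (fire years
  are climate-synchronised in reality), with 20% relative cell-level
  jitter.  This matters numerically: a 14-year per-cell CV estimate has
  irreducible sampling spread proportional to the CV itself, and with
  fully independent cells the highest-CV regime smears across the top
  of every normalised CV column, defeating complete linkage no matter
  how the targets are spaced.  A fully idiosyncratic mode
  (`shared_interannual=False`) exists for pixel-wise trend experiments,
  which assume independent pixels.
* **Linear precipitation coupling.**  Annual burned area responds
  linearly to the antecedent 6- and 24-month precipitation anomalies,
  so the decoupling regression is correctly specified on synthetic data
  and its calibration can be tested cleanly; a multiplicative
  (mis-specified) variant is available for robustness experiments.
* **Planted trends** are geometric, (1 + r)^t, with r the per-year
  fractional change; a planted "slope" in km²/yr is converted as
  r = slope ÷ total.  Over 15 years the OLS estimate of a geometric
  decline is a few percent shallower than the nominal slope (curvature),
  which the recovery tolerances accommodate.
* **Tree-loss anomalies** are planted as per-(regime × class) loss-rate
  multipliers, rescaled so the cover-weighted mean is 1; a stratum
  planted at ratio r then has r times the all-domain loss fraction in
  expectation, which is precisely the statistic the degradation summary
  estimates.  Recovery scenarios must therefore plant strata whose
  cover-weighted mean anomaly is 1 (the shipped scenario adds a
  zero-loss background stratum to balance ratios {1, 2, 4}).

What the generator does *not* emulate: cloud gaps, orbital artifacts,
geolocation error, sub-cell spatial structure, fire spread between
cells, vegetation–fire feedbacks, or any real geography.  Passing
recovery tests therefore demonstrates that the *analysis* is correct and
calibrated under its own assumptions — not that those assumptions hold
for any particular satellite archive.

## Problem sizes and determinism

The shipped experiments use a 20 × 20 lattice (~300 burned cells) for
clustering recovery, 500 independent cells × 15 years for trend
calibration and recovery, 1000 cells per stratum for anomaly recovery,
and a 160 × 160 lattice for the projection experiment — the last because
MESS coverage is reference-size-limited (see above).  All stochastic
draws flow from one seeded `numpy` generator per dataset; identical
configuration and seed give bit-identical outputs, and the pipeline
writes its configuration hash and seed next to every run.

## Known limitations

* MESS false-dissimilar rates are material for small reference regions;
  coverage numbers from small lattices understate true similarity.
* Binary Schoener's D depends on grid resolution; cross-study
  comparisons must fix R and bounds.
* The complete-linkage definition inherits that method's sensitivity to
  outlying cells: a single extreme cell can claim a cluster at small K.
  The diagnostics surface this (singleton clusters, tied heights), but
  the package does not remove outliers for you.
* The decoupled-trend flag identifies change not explained by the two
  precipitation windows; wind, temperature extremes and other weather
  covariates are outside the model, so "anthropogenic" is shorthand for
  "rainfall-decoupled".
* NDVI thresholds are fixed constants acting on normalised values; they
  are not re-derived from the data.
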