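# Methods

This note documents the models, parameter choices and numerical
decisions behind `colonyforage`, and what the simulation-based tests do
and do not establish.

## Behaviour classification and trip segmentation

The classifier is deliberately simple — two deterministic rules, no
hidden-Markov or state-space smoothing — because the downstream
quantities (trip metrics, UDs) only need a flying/foraging split that is
robust at 5–15-minute GPS cadences.

* **Colony rule.** A fix within the splash-down radius is `colony`.
  Defaults: 1000 m (razorbill), 3000 m (murre), 5000 m (kittiwake).
  These radii are species-level descriptions of where birds rest and
  wash near the colony; they are configuration, not estimates.
* **Speed rule.** Instantaneous speed is great-circle distance from the
  previous fix divided by elapsed time, assigned to the segment's later
  fix (classification is causal: the state on arrival). Speeds at or
  above the threshold are `flying`; below, `foraging`. The threshold is
  the harmonic mean of drift (5 km/h) and average flight speed (80 km/h
  auks, 47 km/h kittiwakes): 9.41 / 9.41 / 9.04 km/h, averaged to a
  common 9.29 km/h applied to all species by default (per-species
  thresholds are an option). The first fix of a track has no speed and
  is labelled by the distance rule alone.
* **Cleaning.** Fixes with < 4 satellites are dropped; duplicates are
  exact (bird, timestamp) repeats or consecutive identical
  position+timestamp rows. Unparseable rows are dropped with a logged
  count.
* **Trips.** Maximal runs of consecutive non-colony fixes; runs with
  ≥ 5 fixes are complete trips ("more than four positions" read
  strictly). A time gap exceeding 3× the sampling interval (median fix
  spacing when not supplied) breaks a run — without this, a receiver
  outage at sea would fabricate a long slow "foraging" segment. Runs
  still at sea when the record ends are tagged incomplete and excluded
  from metrics by default.

## Trip metrics

FRI is the mean distance to the colony over foraging-labelled fixes —
an interpretation of "average distance at which birds forage"; it is the
one quantity here whose published definition is by citation only, so it
is implemented as the plain mean and documented as such. The commuting
index uses relative distances X_i = d_i / max-trip-distance over
foraging fixes only; CI = 1 − 2·MAD. Since X ∈ [0, 1] implies
MAD ≤ 0.5, CI ∈ [0, 1] always; for X uniform, E|X − ½| = ¼ gives
CI = 0.5. A "patch" is a maximal foraging run — the only definition the
two-rule classifier supports; an optional centroid merge radius exists
but is off by default. Departure time is the local hour (UTC offset −4
by default) of the first at-sea fix, entered in the PCA linearly (a
sine/cosine pair would handle midnight wrap-around; at this colony
departures cluster in daylight, so the linear encoding is used and the
wrap-around caveat noted).

## Utilization distributions and overlap

* **Projection.** Azimuthal equidistant centred at the colony:
  colony distances are exact, inter-point distortion is negligible at
  ≤ 200 km, and there are no UTM-zone edges to manage.
* **KDE.** Isotropic bivariate normal kernel evaluated at cell centres
  and renormalized over the grid (guaranteeing Σ mass = 1 on any finite
  grid, rather than relying on the analytic 1/(2πh²n) constant).
  Bandwidth is the ad hoc bivariate reference
  h = 0.5(sd_x + sd_y)·n^(−1/6). The default analysis grid is the
  union bounding box of the species pair padded by 3·max(h) — overlap
  indices require one shared discretization. Grid resolution is
  configurable; the pipeline default is 100×100 (250×250 changes BA/UDOI
  in the third decimal at these smoothing scales).
* **Contours.** The L% contour is the smallest cell set by descending
  density whose mass reaches L/100, ties broken by flat cell index for
  reproducibility. Level-conditioned UDs are renormalized within their
  contour (masking without renormalization is available).
* **Randomization.** Species labels are permuted over whole trips
  (preserving group sizes); both UDs are rebuilt per permutation with
  h_ref re-estimated — the bandwidth is part of the estimator being
  permuted (freezing h at the observed values is an option). The
  one-sided empirical p for observed overlap lower than the null is
  (1 + #{null ≤ obs})/(n_iter + 1), which is valid (conservative) under
  exchangeability. A Mann–Whitney rank statistic of the observed value
  against the null sample is emitted alongside, but a single observed
  value against a permutation sample is statistically uninformative
  beyond its rank, so the empirical p is the primary output.

## Diet

Lengths from pixel ratios are scale-invariant in pixels. Allometric
coefficients other than capelin's (a = 2.7e-5, b = 2.76, mass in g,
length in mm) vary by stock and season and must be supplied by the user;
tests and examples use the capelin coefficients for all species, which
is a fixture choice, not a biological claim. "Unknown" prey mass is the
dataset-wide mean of identified item masses (two-pass); a per-predator
mean is available. Frequency of occurrence counts an observation once
per prey species present — the reading under which published totals
(e.g. 146 = 60 + 66 + 19 + 1) are internally consistent. Composition
percentages are reproduced to ±0.02 points rather than string-exact:
published tables appear to truncate rather than round in some cells.

## Synthetic data

The generator emulates exactly the structure the analysis assumes:
straight-line commutes at flight speed (5% relative speed noise),
isotropic Gaussian random walks at patches scaled to drift speed,
colony rest periods inside the splash radius, 5- or 15-minute cadence,
~2% of fixes with < 4 satellites and ~1% duplicated rows. Commute legs
are quantized to whole sampling steps so that arrivals coincide with
fixes and measured step speeds stay in the flight regime. Default
scenario tempo (2 trips/day, 60-min mean patch dwell, patches 10–25 km
out) is loosely matched to reported auk trip durations of roughly 8–18 h
and is illustrative, not calibrated.

It does **not** simulate area-restricted search, drift during commutes,
diel rhythms, tides, wind, or location error beyond the satellite-count
flag. Passing recovery tests therefore shows the estimators are correct
for data meeting the classifier's own assumptions — two separable speed
regimes — not that the assumptions hold for any particular field
dataset.

Diet observations carry true lengths; pixels satisfy
prey_px = bill_px·(L/bill_mm)·(1 + ε) so the length estimator is exact
at ε = 0. Murres are single-prey loaders by construction (load-size
model degenerate at 1); puffins/razorbills use 1 + Poisson(mean − 1)
loads around means of ~3.

## Statistical layer

Rank tests come from scipy (Kruskal–Wallis tie-corrected H; Mann–Whitney
exact for combined n ≤ 25 without ties, continuity-corrected normal
otherwise; Bonferroni = min(1, p·n_pairs)). The mixed model is
statsmodels MixedLM (REML) on log metrics with a bird random intercept;
the species Wald χ² is converted to an F with denominator df
approximated by residual df (n − rank − (n_birds − 1)) — a Satterthwaite
approximation is not available in statsmodels, the method is recorded in
every result, and printed-df replication is not asserted. When every
bird has exactly one trip the random intercept is unidentifiable and the
function falls back to one-way OLS/ANOVA, flagged in the result. PCA is
an eigendecomposition of the correlation matrix (standardized metrics)
with Kaiser retention (eigenvalue > 1). The quasi-Poisson model is a
Poisson GLM with Pearson-χ²/df dispersion.

## Problem sizes used in validation

Simulation-based checks run at sizes chosen to give stable pass/fail
behaviour on a single CPU: the KDE oracle at 50 points on a 40×40 grid
(agreement to 1e-12); permutation calibration at 200 replicate
deployments × 200 permutations on a 40-cell grid (type-I rate ≤ 0.06 at
α = 0.05); the disjoint-range power check at 1000 permutations
(p ≤ 0.002); segmentation recovery on a 4-bird, 2-day, 3-patch scenario
(≥ 90% at-sea agreement, observed ~98%); and type-I calibration of each
statistical test at 500 null replicates with a 3-standard-error bound.

## Known limitations

* The classifier cannot separate surface drift during commuting pauses
  from foraging; both fall below the speed threshold.
* UDs are built from foraging-labelled fixes only by default (an
  all-at-sea mode exists); with 15-min cadences, short patch visits can
  be missed entirely.
* The permutation null treats trips as exchangeable units; trips from
  the same bird are not independent, so with very few birds per group
  the effective null space is small.
* Percent-volume contours are cell sets, not smoothed polygons; GeoJSON
  export emits cell polygons.
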