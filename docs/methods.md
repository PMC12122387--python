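# Methods

## Problem setting

Post-glacial freshwater stickleback populations are compared against
contemporary marine populations standing in for the ancestral form.  The
package quantifies two things for every choice of marine reference: the
magnitude of each lake's divergence and the parallelism (theta angle)
between lakes, and then asks how sensitive both are to the reference
choice, to geographic separation through water, and to climatic
difference.

## Synthetic survey generator

`simulate.generate_specimens` draws a hierarchical Gaussian model:

* **Site means.**  Each site's expected trait value is a habitat base value
  plus, for freshwater sites, a shared offset (the parallel component of
  divergence) plus a site-specific Gaussian deviation of that offset
  (`nonparallel_sd`, the non-parallel component), plus among-site jitter
  applied to both habitats (`among_site_sd`).  Site means are drawn once
  per site, fish-level noise is independent — the same two-level structure
  the downstream mixed models assume.
* **Fish.**  Standard length ~ N(50.71 mm, 7 mm).  Each trait is the site
  mean plus a linear allometric term `slope × (L − 50.71)` plus N(0,
  `trait_sds`).  The two counted traits (lateral plates, gill rakers) are
  rounded to non-negative integers rather than drawn Poisson, so the
  configured variances are honoured; their variances are far from the
  Poisson mean-variance constraint in real surveys.
* **Defaults.**  10 marine and 6 freshwater sites with the classic survey
  layout (20–60 and 25–30 fish per site respectively).  Within-site trait
  SDs take ~70% of realistic marine trait variances, among-site jitter the
  remaining ~30%.  The freshwater offsets encode the canonical
  marine→freshwater contrasts: −25 lateral plates, −1.6 mm pelvic spine,
  −1.8 mm pelvic girdle, −0.8/−0.9 mm dorsal spines, −2.5 gill rakers,
  +1.2 mm body depth.  Site-level means are not published for the real
  survey, so these are field-plausible values fixed once; they are not
  fitted to anything.
* **Climate.**  19 bioclim-style variables are linear combinations of
  three latent factors (a latitude-driven thermal gradient, a
  longitude-driven precipitation gradient, a seasonality factor) plus
  noise, on WorldClim-like scales.  Temperature-level and precipitation
  blocks are collinear (|r| > 0.8) by construction so the pruning step has
  real work to do; the six "annual" summaries carry extra independent
  noise so they survive pruning, as they do in real climatologies.
* **Geography.**  A synthetic coastline raster: an ocean band along the
  west, lakes inland, each connected to the ocean by a carved river, so
  every pair of sites is reachable through water.

**What the generator does *not* emulate:** measurement error/repeatability
structure, non-Gaussian trait distributions, genetic covariance between
traits beyond shared allometry, and — importantly — spatial autocorrelation
of site means.  Because site means are drawn independently of coordinates,
the true distance-decay slope is zero: passing distance-decay fits on
synthetic data show only that the machinery is calibrated (no spurious
slope), not that the package would detect a real decay, which is instead
exercised by the parameter-recovery tests at the model level.

## Size correction

`γᵢ = χᵢ − β(Lᵢ − L̄)` per trait.  `β` is fitted per population by default
(slopes genuinely differ among sites); a pooled common slope is available.
`L̄` is the grand mean standard length of the entire dataset — the equation
names a single average, so no per-group centring.  Exemptions follow the
convention for this system literally: gill rakers never corrected, lateral
plates corrected only in freshwater fish (marine fish are fully plated).
The asymmetric plate rule is biologically debatable and is therefore a
visible config switch (`exempt_plates_globally`).  Correction is idempotent
in effect: re-fitting allometry on corrected traits returns slopes below
1e-8, which the suite asserts.  Missing trait values propagate untouched.

Variance homogeneity between habitats uses Levene's test, median-centred
(Brown–Forsythe) by default — the default of the standard regression
packages — with mean-centring available and recorded in the output.

## Morphospace and vectors

One PCA over all specimens jointly (marine + freshwater) so all sites share
a coordinate system; correlation matrix by default because the traits mix
millimetres and counts.  Determinism conventions: the largest-magnitude
loading on each axis is positive, and PC1 is oriented so freshwater mean >
marine mean.  Centroids are per-site mean scores.

Divergence vectors are freshwater-minus-marine centroid differences.  The
default axis set is **all** PCs (a full-rank rotation of trait space, so
vector geometry is that of the z-scored trait space); a restricted set
(e.g. PCs 1–3) is a parameter, and outputs record which was used.  Theta is
computed with the numerically stable half-angle formula
`2·atan2(‖u−v‖, ‖u+v‖)` on unit vectors, reported in degrees; a
zero-length vector raises an error rather than fabricating an angle.  The
panmictic reference pools all marine specimens under one label and reuses
the same PCA scores, so its centroid is exactly the sample-size-weighted
mean of the marine site centroids.

## Reference-effect models

The pairwise divergence table (every reference × every lake) is a complete
balanced two-way layout, so `reference_effect_test` computes the mixed
model divergence ~ reference + (1 | lake) in closed form:
`F = MS_ref / MS_resid` with `(r−1, (r−1)(f−1))` degrees of freedom, and
the lake variance via the ANOVA estimator `(MS_lake − MS_resid)/r`
(truncated at zero), with the standard large-sample SE.  For balanced data
this coincides with REML; the suite cross-checks it against statsmodels
MixedLM.  The closed form also makes permutation calibration cheap — the
Type-I test permutes values across references within each lake 99 times
per replicate over 200 replicates.

One degenerate case is worth knowing: when every freshwater centroid lies
on one side of every marine centroid on PC1 (complete habitat separation,
the usual situation with real divergence), `|c_f − c_m|` is *exactly
additive* in the row and column effects, the residual SS is numerically
zero and F is unbounded.  The statistic is reported as computed (`inf`);
the vector-length and theta models, whose responses are nonlinear in the
centroids, are the informative reference-effect tests in that regime.

General mixed fits (distance decay) go through statsmodels MixedLM (REML),
falling back across optimisers at the variance boundary and flagging
non-convergence.  Denominator df use the between-within (containment)
convention `n − rank − n_groups + 1`; fixed-effect SS are reported on the
residual-variance scale (`SS = F·q·σ²`), matching standard mixed-ANOVA
tables.  Predictors in the distance-decay drivers are standardised, so
slopes are per-SD of distance/climate difference.  Marine-only models
(pairwise morphological distance among marine sites vs distance) are
simple OLS — with one observation per site pair there is no grouping
factor to absorb.

Percent change under reference substitution is `100 × (max − min)/max` per
lake — normalising by the maximum is the only convention that keeps the
statistic bounded by 100%; `min` and `mean` normalisations are available
and labelled in output.

## Waterway distance and climate

Distances are shortest paths over the boolean water raster, 8-connected
with √2 diagonal cost (4-connectivity would overestimate diagonal
channels; connectivity is a parameter), via sparse Dijkstra.  Coordinates
snap to the nearest water cell within 3 cells (logged); unreachable pairs
raise a "disconnected" error instead of returning infinity.  Raster I/O is
a plain ASCII grid.

Bioclim pruning walks a priority list — annual trends and overall
variation first (BIO01, BIO12, BIO02, BIO03, BIO15, BIO08, then the rest
ascending) — keeping a variable unless |r| > 0.80 with one already kept;
constant variables are dropped with a warning.  The retained set feeds a
site-level correlation-matrix PCA, and environmental difference per site
pair is the absolute score difference on the requested axes (PC1–PC2 by
default).

## Numerical and testing choices

* Every stochastic step is driven by `numpy.random.default_rng` seeded from
  a single run seed; per-module streams are forked from it, and all CSV
  output uses 12 significant digits so byte-identity across reruns is
  meaningful (asserted in the suite).
* Problem sizes in the suite: parameter-recovery experiments use 20
  surveys at 60 fish/site (theta recovery), 200 replicates × 99
  permutations (Type-I calibration), and 50 replicates (variance
  recovery) — sizes at which Monte-Carlo error is a small fraction of the
  tolerances asserted.
* Property tests (rotation invariance of theta, Levene shift invariance,
  pruning row-order invariance, Dijkstra vs exhaustive enumeration on tiny
  grids) run on fixed-seed randomness so failures reproduce.

## Known limitations

* The closed-form reference test assumes a complete pairs table; lakes
  with missing cells are dropped (logged), not modelled.
* Waterway distances depend on raster resolution; the discretisation error
  is bounded by the √2 connectivity factor but not corrected.
* The generator's climate is only a 3-factor sketch; it supports the
  pruning/PCA machinery but carries no real climatology.
* p-values from the containment-df convention are approximate for
  unbalanced general mixed fits; they are reported, never used for control
  flow.
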