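# Methods

`lagbeta` analyzes multi-year community-fingerprint time series — samples ×
bands tables of relative intensities, as produced by gel fingerprinting of
soil microbial communities — and asks two questions: *how much* does a
community turn over through time, and *is that turnover directional or
stochastic*; and which measured soil variables structure the composition.

## Data model

A study consists of three tables joined on a sample key:

* **fingerprint** — samples × bands, non-negative intensities, rescaled to
  relative abundances (row sum 1) on load by default.  Band tables carry no
  absolute-abundance information, so every downstream statistic renormalizes
  internally and the normalization flag is provenance only.
* **metadata** — site, sampling date (day precision; month-only inputs map
  to the 15th so lags are deterministic), replicate index, texture class
  (`sandy`/`clayey`).
* **chemistry** — pH (unitless), ammonium and nitrate (mg/kg), organic
  matter, clay and moisture (%), keyed per sample or per (site, date); the
  latter broadcasts to all replicates of that date.  Missing cells are
  permitted and propagate pairwise-complete into the correlation screens.

Replicate lanes of one sampling date are averaged into a **composite
profile** (mean of relative-abundance vectors, renormalized) before any
between-date statistic; the alternative policy of keeping replicates as
separate samples is exposed (`policy="separate"`) and the default is
recorded in output provenance.  Composites keep between-date comparisons
from being inflated by replicate scatter.

## Diversity

* Shannon index H′ = −Σ pᵢ ln pᵢ in nats (natural log; base 2 available).
  On 20–60 detected bands this puts H′ in the ≈1.7–4.1 range typical of
  fingerprint studies.
* Band richness = count of bands above a detection epsilon (default 0,
  because gel band-calling has already thresholded).
* Temporal β-diversity of a site = mean of all T(T−1)/2 pairwise
  Bray–Curtis dissimilarities (Σ|aᵢ−bᵢ|/Σ(aᵢ+bᵢ)) among its date
  composites.  0 = static community, →1 = complete turnover.  It uses no
  temporal ordering, so it measures the *amount*, not the *direction*, of
  change.

## Time-lag analysis (TLA)

For each site, every unordered pair of dates contributes a point
(√lag, distance); ordinary least squares of distance on √lag gives the
turnover rate.  The √lag axis keeps the few long-lag pairs from dominating
the fit.  Distances default to the Hellinger distance (Euclidean distance
between rows of √relative abundance, bounded by √2); Bray–Curtis is
available behind the `metric` flag.  Lags are measured in months of
30.44 days by default (configurable to days/years); the unit only rescales
slopes.  A `distance_scale` factor is exposed for percentage-scale axes.

The *overall* analysis pools all sites' pairs into a single regression, so
its R² is computed over all points; averaging per-site slopes is available
as `mean_slope`.

**Significance.**  The classical parametric p comes from the OLS slope
t-test.  Because the pairs of one series share composites they are not
independent, so a permutation p is reported alongside.  The default scheme
permutes the *date labels* within each series and recomputes the lags while
keeping the distance matrix fixed (a Mantel-style test).  This respects the
correlation between distances that share a composite: on 500 simulated
zero-drift series it rejects at the nominal 5% level (measured ≈0.05),
which is the package's calibration requirement.  A simpler scheme that
shuffles the distance multiset over the fixed √lag design is retained
(`scheme="shuffle"`) but is conservative (measured ≈0.02 under the same
null) precisely because it destroys that sharing structure; it is kept for
comparison, not inference.  p-values use the add-one rule
p = (1 + #{|slope*| ≥ |slope|}) / (1 + n_perm), so p is never 0.
Degenerate input (constant distances) returns a flat fit (slope 0, R² 0,
p 1) rather than NaN.

## Constrained ordination

CCA follows the chi-square/weighted-averaging formulation.  With the table
rescaled to proportions P, row masses r and column masses c, the
correspondence residual matrix is

    q̄ᵢⱼ = (pᵢⱼ − rᵢcⱼ) / √(rᵢcⱼ),

whose total sum of squares is the total inertia.  Environmental variables
are standardized to weighted mean 0 / variance 1 (making biplot arrow
lengths comparable), mapped into the row-mass metric, and an orthonormal
basis of the weighted predictor space is built by SVD with a rank cut at
1e−10 relative tolerance; the singular values of the projected residual
matrix are the constrained eigenvalues.  Scores use type-2 scaling (band
scores carry the eigenvalues); linear-combination and weighted-average site
scores and weighted-correlation biplot arrows are exported.

* **Partial CCA**: the covariables' weighted fit is removed from both q̄
  and the focus predictors; the constrained inertia of the residual
  projection is the focus set's *unique* contribution, reported as a
  fraction of the original total inertia so fractions are comparable across
  focus sets.
* **Permutation test**: pseudo-F = (constrained/q)/(residual/(n−q−c−1)),
  with reduced-model permutations — the covariable-residualized focus
  predictors are row-permuted in sample space, re-weighted, re-residualized
  and re-projected.  Under a composition-independent predictor the p-value
  is uniform (Kolmogorov–Smirnov check in the acceptance suite).
* **Forward selection**: greedy on conditional added fraction; a candidate
  is retained only if its conditional permutation p ≤ α (default 0.05,
  999 permutations).  With α ≥ 1 the trace reduces to pure greedy ordering.
* **Variance partitioning** reports each variable's unique fraction (that
  variable constrained, all others covariables), the joint explained
  fraction and the residual.  Shared fractions are derivable from these but
  not emitted.  Perfectly collinear duplicates legitimately get unique
  fraction 0 without changing the joint fraction.

Saturated designs (predictor rank ≥ n−1, or no residual degrees of freedom)
and constant predictors are rejected rather than silently fitted.

## Correlation screens

Every variable except pH is log(x+1)-transformed before Pearson
correlation (pH is already a log-scale quantity); the transform applied per
variable is recorded in the output.  Missing data are handled
pairwise-complete; pairs with fewer than 3 complete observations are
reported with NaN statistics.  Raw two-sided p-values mirror the classical
significance-star convention; a Benjamini–Hochberg q column is emitted in
addition because a 15+ cell grid of uncorrected tests is a known caveat.
The default observation units are (site, date) composites for α-diversity
and per-site values for temporal β and the TLA slope (correlated against
site-mean chemistry).

## Synthetic data generator

The generator emulates a realistic full-scale study design — 8 sites (5 sandy/acid,
3 clayey/near-neutral) × 11 sampling dates spread over three calendar years
(4 + 3 + 4 campaigns) × 4 replicate lanes, with a ~120-taxon latent pool —
and smaller desk-scale variants (3 × 6 × 2) for fast tests.  Latent
per-taxon log-abundances combine:

* a site-specific baseline (Normal, sd 1.2 → realistic unevenness);
* **directional replacement** at rate θ per month: a random half of the
  pool drifts up and half drifts down linearly in time, shifting
  probability mass from "resident" to "incoming" taxa.  Replacement rather
  than a biomass trend, because TLA detects compositional turnover;
* an optional per-taxon random walk (`walk_sd`, default 0) for
  autocorrelated stochastic turnover — kept separate from θ so the null
  preset has exactly exchangeable dates;
* a shared seasonal sinusoid (peak mid-April) with per-taxon loadings,
  amplitude 0.4 log-units by default;
* chemistry linkage: standardized chemistry values shift a responsive 25%
  taxon subset with a stated effect size (log-units per sd of the
  variable);
* i.i.d. replicate noise (Normal on the log scale, sd 0.5 — chosen so
  desk-scale null series yield temporal β ≈ 0.3–0.5, the plausible
  fingerprint range).

Observation censors each lane at a relative-abundance detection limit
(default 1%, the upper end of the commonly cited 0.1–1% fingerprint
sensitivity), renormalizes survivors, and drops never-detected taxa from
the band table.  Censoring preserves rank order and is monotone in the
detection limit.  A lane censored to zero bands is regenerated with fresh
replicate noise and flagged.  Chemistry mimics the field pattern: static
per-site pH and clay set by texture class, nitrate/ammonium high in spring
and low in autumn with site-level multipliers, mildly varying organic
matter and moisture.

What the generator does *not* emulate: gel-to-gel band alignment error,
co-migration of distinct taxa into one band, saturation of intense bands,
phylogenetic structure among taxa, and real nitrogen-cycling dynamics.
Passing tests therefore demonstrate that the statistics recover known
truth under an idealized fingerprint model, not that any biological
conclusion transfers to a particular field dataset.

## Problem sizes used in validation

The test and acceptance workloads run the desk-scale geometry: 500-series
null calibrations (199 permutations each), a drift grid
θ ∈ {0, 0.02, 0.05, 0.08}/month with 100 replicates per level, and 200
forward-selection recovery replicates (999 permutations, effect size 1.2
log-units/sd against four noise candidates).  Full-scale (352-sample)
analyses are run once per seed in the acceptance script.  These sizes give
binomial standard errors of ~1% on calibration rates while keeping the
whole validation run to a few minutes on one core.

## Known limitations

* The parametric TLA p-value inherits the classical pair-dependence caveat;
  it is reported because it is the field convention, but the permutation p
  is the defensible one.
* Temporal β and TLA operate on composites; with `policy="separate"` the
  per-date replicate structure is preserved for diversity but TLA still
  requires one profile per date.
* The loader stays agnostic about upstream band-calling choices
  (background subtraction, presence/absence coding); it records only the
  normalization it applied itself.
* Correlation screens at the site level have as many observations as sites;
  with few sites these r values are descriptive, not inferential.
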