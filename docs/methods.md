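# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical and design choices behind `holcbio`.

## Study design being emulated

The package analyzes contributory wildlife observations (one record = one
identified organism at a time and place) within HOLC-graded urban
neighborhoods. The unit of analysis is the neighborhood polygon, attributed
with its city, HOLC grade (A–D, A the reference), planar area in km², mean
impervious-surface percentage, and its observation count. Three questions
are addressed: how fast unique species accumulate with effort per grade,
how expected species richness differs by grade after controlling for
effort, area, and urban intensity, and whether grades hold distinguishable
species assemblages.

## Ingest and filtering

Records pass a fixed rule chain, each step counted in a `FilterReport`
(retained + dropped = input at every rule):

1. quality — only research-grade records;
2. species present — records without a species name are dropped;
3. date window — half-open [start, end), default 2017-01-01 to 2022-01-01.
   The half-open convention is a deliberate choice where the window's
   endpoint is ambiguous.

Points are assigned to polygons boundary-inclusively (a point on a shared
edge goes to the lexicographically lowest neighborhood id, logged); records
outside every polygon are dropped and counted. A city is retained only if
every grade × clade cell (4 × 6) holds at least `min_per_cell` records
(default 5). Geometry is planar throughout: synthetic data lives in km
coordinates, and real data must be projected before ingest; this keeps the
core free of geodesic dependencies. Zonal impervious means average grid
cells whose centers fall inside the polygon, falling back to the nearest
cell for slivers (logged).

Species are distinct exact strings; no taxonomic resolution is attempted.
Records with unknown establishment status count toward overall richness but
neither the native nor the nonnative subset.

## Accumulated species richness

A stratum's curve S_k increments exactly when record k's species is unseen
among records 1..k−1. The default order is chronological (date, then record
id) — the only order reconstructible from the data; permuted-order curves
(seeded) are available, and their mean is validated against the closed-form
rarefaction expectation E[S_k] = Σ_s [1 − C(N−n_s, k)/C(N, k)]. The delta
statistic is the difference in observations needed to reach the reference
grade's final richness; strata that never reach it are flagged rather than
extrapolated (no Chao/ACE estimators).

## Richness model

    y_i ~ Poisson(μ_i),
    log μ_i = offset_i + β0 + u0_c + (β_g + u_gc) + β_imp x_i,
    offset_i = log(area_i) + log(n_obs_i),
    β* ~ Normal(0, 2),  u*_c ~ Normal(0, σ*),  σ* ~ Gamma(1, 1).

Notes on the contested choices:

- **Offset.** log(area) + log(n_obs), i.e. the log of the exposure product —
  the standard effort-and-exposure offset. The alternative reading
  log(area + n_obs) is implemented behind `offset_mode="sum"`. Only β0 is
  affected by the unit of area (an area rescaling by c shifts β0 by −log c;
  verified as a test invariant).
- **Grade coding.** Treatment coding with A as reference; u_{A,c} ≡ 0.
- **Impervious scaling.** z-scored over included neighborhoods, so the
  Normal(0, 2) prior is on a per-SD effect.
- **Zero-effort neighborhoods.** Excluded (the offset is undefined at
  n_obs = 0); no pseudo-count padding.
- **Contrast scale.** Grade contrasts are differences of grade-level
  expected richness on the response scale (species units), summarized by
  the posterior median and central 95% interval; "significant" means the
  interval excludes zero. No multiplicity correction is applied across the
  six grade contrasts (BH is used only in the beta-diversity family).
- **Grade-level summaries.** At city level, the per-draw average of μ_i
  over the city's neighborhoods of that grade. At the overall ("ALL")
  level, the model is marginalized over a hypothetical new city whose
  deviations are drawn from the fitted Normal(0, σ) distributions at the
  grade's average offset and impervious value; these intervals are wider
  than any within-city interval because they carry between-city variance.
  With only four observed cities the σ posteriors retain heavy prior tails,
  so marginal "ALL" contrasts are very wide at this scale; end-to-end
  checks therefore evaluate contrasts at the city (conditional) level.

### Sampler

An adaptive Metropolis-within-Gibbs kernel (numba-jitted) on a working
parameterization with non-centered city deviations (u = σz, z ~ N(0,1)) and
log-scale SDs (change-of-variable Jacobians included, so the stationary
distribution is exactly the model posterior). Three move families:

1. single-site Gaussian random-walk updates, scales adapted to a 0.44
   acceptance rate by Robbins–Monro during burn-in and frozen afterwards;
2. a joint adaptive-Metropolis update of the five fixed effects. Impervious
   surface is grade-structured, so β_imp is nearly collinear with the grade
   effects; the proposal covariance is seeded with the penalized-IRLS
   (Laplace) covariance of the fixed effects and then moment-adapted,
   which is what makes the short test profile mix;
3. likelihood-invariant interweaving moves per effect group: a translation
   (b → b+d, z → z − d/σ) and a rescaling (log σ → log σ + d, z → z·e^{−d},
   with the e^{−Cd} proposal Jacobian), which decorrelate the b–u ridge and
   the σ–z funnel.

Chains start from overdispersed prior draws (re-drawn up to 100 times until
the posterior is finite) and are bit-reproducible given the seed.
Convergence uses the classic potential scale reduction factor
R̂ = √((n−1)/n + B/(nW)) per parameter, pass threshold 1.10. The default
configuration mirrors the full-scale analysis (110,000 burn-in, 40,000
draws per chain, 4 chains); the test profile (2,000 + 2,000 × 4) is used
for all desk-scale runs and converges on the default synthetic scale in
roughly a second per fit. Deviation SDs can be pinned (e.g. at 10⁻⁶) to
recover the fixed-effects GLM limit, which is validated against an IRLS
oracle.

## Beta diversity

Presence–absence matrices per subset (all/native/nonnative); Jaccard
dissimilarity d = 1 − |A∩B|/|A∪B| (0 = identical assemblages — the
conventional dissimilarity direction; prose that maps 0 to "completely
dissimilar" describes similarity and is not followed). PERMANOVA uses
sequential (Type-I) sums of squares with term order (city, grade), matching
the default of the classical adonis interface, via the Gower-centered inner
product G = −½CAC and per-term projector traces; pseudo-F_t =
(SS_t/df_t)/(SS_res/df_res). p-values come from free row/column permutation
with the "+1 include the observed" convention, or exhaustive enumeration
for n ≤ 8. Pairwise grade tests are restricted to one city at a time
(two-group PERMANOVA), with BH correction across that city's six pairs;
pairs with fewer than two neighborhoods in a grade are reported untestable.
No dispersion (PERMDISP) test and no ordination plots.

## Synthetic-data generator

What it emulates: four cities × four grades × 11 neighborhoods each
(176 total, a quarter of the ~700-neighborhood full-scale study, with a
704-neighborhood configuration exercised in tests); rectangular
non-overlapping neighborhoods of 0.5–2.5 km² on per-city grids; impervious
surface averaging 35/45/55/65% for grades A–D with 5% cell noise; six
clades with bird-dominated weights; ~70% native species;
negative-binomial per-neighborhood effort (mean 150, dispersion 5 — heavy
tailed, ~26k records per run at default scale); geometric-series
rank-abundances (shape 0.03); nested grade pools (sizes 160/130/100/70,
adjacent-grade overlap 0.7) with per-city species substitution
(city overlap 0.7). Pool sizes decrease from A to D so record-mode data
carries the redlining richness gradient; the generative model-mode truth
(β0 = −2.2, β_B = −0.33, β_C = −0.55, β_D = −1.30, β_imp = −0.1,
σ0 = 0.5, σ_slope = 0.3) mirrors the magnitude ordering of the full-scale
richness tables.

City pools are built by substituting each master species with a
city-specific counterpart with probability 1 − city_overlap. This preserves
the within-city grade-overlap structure exactly: with pool_overlap = 1 all
grade pools inside a city are identical (the exact null used for type-I
calibration), and with pool_overlap = 0 grade pools are disjoint.

What it does not emulate: observer movement and spatial clustering of
effort (records are uniform within polygons), taxonomic misidentification,
temporal trends, irregular polygon shapes, and real spatial autocorrelation
of communities. Passing tests therefore demonstrate the statistical
machinery under a correctly specified or cleanly structured data-generating
process, not robustness to every bias of real contributory data.

## Validation problem sizes

The simulation-based checks run at sizes chosen to make their Monte-Carlo
error small relative to the tested margins: 100 datasets for the
PERMANOVA–ANOVA identity; exhaustive permutation enumeration up to n = 7;
500 null datasets (2 cities × 12 neighborhoods, 999 permutations) for
type-I calibration; 200 permuted curves × 10 communities for the
rarefaction oracle; 50 replicates at the default region scale for 95%-CI
coverage of (β_B, β_C, β_D, β_imp); 20 end-to-end replicates for grade-
ordering, contrast, and pairwise-PERMANOVA power. The end-to-end power
replicates use deliberately strong, well-separated conditions (pools
280/170/100/50, abundance shape 0.01, effort dispersion 20, disjoint
grade pools) so that "strictly decreasing grade richness" holds with a
margin well above the between-replicate wobble of grade means.

## Known limitations

- Random-walk MCMC, not gradient-based: adequate at these scales, but the
  paper-scale profile is slow by design (hours, not minutes).
- With four cities, σ posteriors are prior-dominated; marginal "ALL"
  summaries are honest but wide, and their Monte-Carlo noise is visible in
  the reported medians.
- The sequential-SS PERMANOVA assumes exchangeability under free
  permutation; no restricted/strata permutation schemes are provided.
- Exact-string species identity; no synonym resolution.
- Planar geometry only; the package never reprojects coordinates.
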