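# holcbio

Statistical tooling for studying how historical HOLC ("redlining")
neighborhood appraisal grades relate to urban wildlife biodiversity in
contributory (iNaturalist-style) occurrence data.

In the 1930s the Home Owners' Loan Corporation graded US urban neighborhoods
from A ("greenlined") to D ("redlined"). Those grades still predict
present-day environmental quality, and ecologists increasingly ask whether
they also predict who shares the city with wildlife. Answering that from
contributory occurrence records requires careful statistics: observation
effort is wildly uneven across neighborhoods, neighborhoods differ in area,
and urban intensity confounds the grade signal. `holcbio` packages the three
analyses this question needs — species-accumulation comparisons, a
hierarchical Bayesian model of neighborhood species richness, and
permutational comparisons of species assemblages — together with a
synthetic-data generator so every stage can be validated against known
ground truth without downloading any external data.

## What it computes

**Accumulated species richness.** Within each HOLC grade, the cumulative
count of unique species as observations accrue (a collector's curve). Grades
are compared by the observations needed to reach the reference grade's
maximum richness; the difference is the delta statistic Δ. A closed-form
hypergeometric rarefaction expectation,
E[S_k] = Σ_s [1 − C(N−n_s, k)/C(N, k)], serves as the analytic oracle for
permutation-averaged curves.

**Alpha diversity (richness model).** Per-neighborhood species counts y_i
are modeled as

    y_i ~ Poisson(μ_i)
    log μ_i = log(area_i) + log(n_obs_i)            # offset
            + β0 + u0_{city(i)}                      # random intercept
            + β_g + u_{g,city(i)}                    # grade effect, random slope
            + β_imp · x_i                            # impervious surface (z-scored)

with grade A as the reference level, Normal(0, 2) priors on fixed effects,
and Gamma(1, 1) priors on the four random-effect SDs. Sampling uses an
adaptive Metropolis-within-Gibbs kernel (numba-accelerated) with
likelihood-invariant interweaving moves and a Laplace-preconditioned joint
update of the fixed effects; convergence is checked with the classic
Gelman–Rubin R̂ at a 1.10 threshold. The model yields per-neighborhood
predictions, grade-by-city richness summaries, and grade contrasts on the
response scale with 95% credible intervals.

**Beta diversity.** Neighborhood × species presence–absence matrices,
Jaccard dissimilarities (0 = identical assemblages), and a sequential-SS
(adonis-style) PERMANOVA with terms city then grade: Gower-center the
squared distances, partition by hat-matrix traces, and compare pseudo-F
against free permutations (exhaustive enumeration for tiny n). Pairwise
grade tests run within each city with Benjamini–Hochberg correction across
the six grade pairs.

**Synthetic data.** Rectangular graded neighborhoods laid out in planar-km
cities with an impervious-surface grid (ESRI ASCII); either richness counts
drawn directly from the model above (known parameters) or full observation
records drawn from nested grade/city species pools with geometric-series
abundances and negative-binomial per-neighborhood effort.

## Worked example

`examples/03_richness_model.py` simulates richness for 176 neighborhoods
(4 cities × 4 grades × 11) from known parameters and refits:

```
max Gelman-Rubin R-hat: 1.007 (converged: True)

Posterior medians vs. generating truth (log scale):
  b_B: -0.602 (-1.224, +0.078) truth -0.330
  b_C: -0.720 (-1.441, -0.005) truth -0.550
  b_D: -1.644 (-2.850, -0.363) truth -1.300
  b_imp: +0.018 (-0.292, +0.365) truth -0.100

Grade-level expected richness (city level, median and 95% CI):
  city holc_grade  mean_richness  lower  upper
City01          A          24.62  21.61  27.43
City01          B          25.96  23.07  28.97
City01          C          16.52  14.38  19.07
City01          D           2.43   1.62   3.41
...
```

Every 95% interval covers its generating value; the redlining effect b_D
(here a 73% richness reduction, e^-1.3) is recovered with the correct sign
and magnitude, and grade-D rows show the lowest expected richness in every
city. The other examples demonstrate region simulation, accumulation
deltas, beta diversity, and the end-to-end pipeline
(`holcbio run-all --config config.json` on the command line).

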