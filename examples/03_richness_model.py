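"""Fit the hierarchical Bayesian Poisson model of neighborhood richness.

Simulates richness counts directly from the model with known parameters,
refits, and prints convergence diagnostics, grade-level summaries, and
grade contrasts — the machinery behind the grade-by-city richness tables.
"""

import numpy as np

from holcbio import alpha, synthetic

region = synthetic.make_region(synthetic.RegionConfig(), seed=11)
truth = synthetic.TruthParams()
richness, realized = synthetic.simulate_richness(region, truth, seed=12)

data = alpha.build_model_data(richness)
samples = alpha.sample_posterior(data, mcmc=alpha.McmcConfig.test_profile(seed=13))

report = alpha.convergence_report(samples)
print(f"max Gelman-Rubin R-hat: {max(report.rhat.values()):.3f} "
      f"(converged: {report.passed})")

draws = samples.natural_draws()
print("\nPosterior medians vs. generating truth (log scale):")
for name, true_val in [("b_B", truth.b_grade["B"]), ("b_C", truth.b_grade["C"]),
                       ("b_D", truth.b_grade["D"]), ("b_imp", truth.b_imp)]:
    x = draws[name].ravel()
    print(f"  {name}: {np.median(x):+.3f} "
          f"({np.percentile(x, 2.5):+.3f}, {np.percentile(x, 97.5):+.3f}) "
          f"truth {true_val:+.3f}")

print("\nGrade-level expected richness (city level, median and 95% CI):")
print(alpha.summarize_grades(samples, data, level="city").round(2).to_string(index=False))

print("\nGrade contrasts (response scale; significant = CI excludes 0):")
print(alpha.grade_contrasts(samples, data, level="city").round(2).to_string(index=False))

# The grade-D effect is strongly negative (redlined neighborhoods hold fewer
# species at matched effort and area), and each 95% interval should cover
# its generating value.
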