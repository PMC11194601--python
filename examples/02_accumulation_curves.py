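"""Species-accumulation comparison between HOLC grades.

Accumulates unique species as observations accrue within each grade and
reports how many observations each grade needs to match grade A's maximum
richness (the delta statistic): a positive delta means unique species are
found with more effort than in greenlined neighborhoods.
"""

from holcbio import accumulation, synthetic

region = synthetic.make_region(synthetic.RegionConfig(), seed=1)
# grade A holds the smallest total pool (its curve saturates first), so the
# other grades reach A's maximum richness only with extra observations
comm = synthetic.CommunityConfig(
    pool_size_by_grade={"A": 120, "B": 160, "C": 180, "D": 140},
)
records = synthetic.as_ingested(
    synthetic.simulate_observation_records(region, comm, seed=2)
)

curves = accumulation.curves_by(records, region.neighborhoods)
comparison = accumulation.compare_to_reference(curves, reference="A")
print(comparison.to_string(index=False))

# S_star is grade A's final richness; obs_to_reach is the observation count
# at which each grade first accumulates that many species ("unreached" rows
# have delta = NaN); delta is the extra effort relative to grade A. A
# positive delta means unique species accrue more slowly than in grade A
# (the redlining signature); here the deltas are negative because the
# lower-grade pools are larger and equally even, so they yield unique
# species faster than grade A's small pool.
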