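"""The shuffling null: how much trend does demography alone produce?

Permutes recruitment years among the sampled trees (each tree keeps its
growth rate and its age at the size class) 500 times and compares the
observed apparent trend with the resulting null distribution.
"""

import dendrobias as db

pop = db.simulate_population(
    db.RecruitmentSpec.unimodal(1900, 20, 200), db.GrowthParams(), 2010, seed=1
)
records = db.build_dataset(pop, db.SamplingDesign(class_centers_cm=(27.0,)))

apparent = db.fit_loglinear_trend(records)
null = db.estimate_shuffled_trend(records, n_reps=500, seed=2)
excess, verdict = db.compare_apparent_vs_shuffled(apparent, null)

print(f"apparent trend:        {apparent.slope_pct_per_decade:+.2f} %/decade")
print(
    f"shuffled (null) trend: {null.mean_slope_pct_per_decade:+.2f} "
    f"+- {null.sd_slope_pct:.2f} %/decade over {null.n_reps} permutations"
)
print(f"null t-test vs 0:      p = {null.t_p_value:.2g}")
print(f"excess over null:      {excess:+.2f} %/decade -> {verdict}")
print()
print(
    "The apparent trend sits inside the null band: the whole negative trend\n"
    "is explained by the recruitment-time distribution, not by any real\n"
    "change in growth."
)
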