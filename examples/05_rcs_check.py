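"""Size-based Regional Curve Standardization does not remove the bias.

Standardizes each ring by the population-mean growth expected at the
tree's diameter and regresses the pooled log indices on calendar year
(restricted to diameters every tree traverses, with tree-clustered
standard errors).  Under clustered recruitment the RCS trend is still
significantly negative; under wide uniform recruitment it is flat.
"""

import pandas as pd

import dendrobias as db


def rcs_trend_for(spec, apply_filter, seed):
    pop = db.simulate_population(spec, db.GrowthParams(), 2010, seed=seed)
    if apply_filter:
        pop = db.select_sampled_trees(pop, db.SamplingDesign(class_centers_cm=(27.0,)))
    curve = db.build_regional_curve(pop)
    idx = pd.concat([db.standardize_trajectory(t, curve) for t in pop])
    return db.rcs_trend(idx, max_diameter_cm=27.0)


clustered = rcs_trend_for(db.RecruitmentSpec.unimodal(1900, 20, 400), True, seed=3)
uniform = rcs_trend_for(db.RecruitmentSpec.uniform(1700, 1990, 400), False, seed=4)

print(
    f"clustered recruitment + census filter: "
    f"{clustered.slope_pct_per_decade:+.2f} %/decade (p = {clustered.p_value:.2g})"
)
print(
    f"uniform recruitment, no filter:        "
    f"{uniform.slope_pct_per_decade:+.2f} %/decade (p = {uniform.p_value:.2g})"
)
print()
print(
    "Switching from size-class isolation to RCS detrending changes the\n"
    "magnitude but not the existence of the demographic artefact."
)
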