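"""A real growth increase can vanish inside the demographic bias.

Imposes a genuine linear +10 %/decade stimulation from 1975 on the same
clustered demography and shows that the size-class trend still comes out
negative or flat — the artefact masks the real signal.
"""

import dendrobias as db

spec = db.RecruitmentSpec.unimodal(1900, 20, 200)
design = db.SamplingDesign(class_centers_cm=(27.0,))

for pct in (0.0, 5.0, 10.0):
    stim = db.StimulationSpec(start_year=1975, pct_per_decade=pct) if pct else None
    pop = db.simulate_population(spec, db.GrowthParams(), 2010, seed=3, stimulation=stim)
    est = db.fit_loglinear_trend(db.build_dataset(pop, design))
    print(
        f"true stimulation {pct:5.1f} %/decade since 1975 -> "
        f"apparent trend {est.slope_pct_per_decade:+.2f} %/decade (p = {est.p_value:.2g})"
    )

print()
print(
    "Even a +10 %/decade stimulation - larger than the growth increases\n"
    "reported by plot monitoring networks - fails to show up as a positive\n"
    "size-class trend under this age structure."
)
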