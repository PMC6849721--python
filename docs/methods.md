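# Methods

This note documents the models, conventions, numerical choices and
limitations behind `dendrobias`.

## Growth model

Each tree's annual diameter increment (cm/yr) is

    inc_{i,t} = min( exp(μ + u_i + e_{i,t}), c ),
    u_i ~ N(0, σ_tree²),     e_{i,t} = ρ e_{i,t−1} + N(0, σ_year²),

with the AR(1) deviation started from its stationary distribution so the
first ring is statistically like any later ring. `u_i` is a permanent
tree effect ("a fast grower stays fast"); `e_{i,t}` is autocorrelated
year-to-year variation (climate, canopy dynamics); `c` caps physically
implausible increments. Increments are *diameter* increments, i.e. twice
the radial ring width; ring-width inputs are doubled (and mm converted
to cm) on read.

**Calendar convention.** The ring formed in year *t* counts toward the
end-of-year diameter of year *t*; the recruitment year is the year of
the first ring; age in year *t* is `t − recruitment_year + 1`; hence
`year_at_class = recruitment_year + age_at_class − 1` everywhere.
Diameter crossings are whole-year ("first year with end-of-year diameter
≥ D"); there is no sub-annual interpolation, because rings are annual.

**Default parameters and their calibration.** Defaults are
μ = ln(0.45 cm/yr), σ_tree = 0.14, ρ = 0.6, σ_year = 0.25, c = 3 cm/yr.
They were calibrated jointly against three observable properties of the
reference experiment (recruitment ~ Normal(1900, 20 yr), census 2010 at
≥ 27 cm, growth measured in a 4-cm window at 27 cm):

- mean spurious trend ≈ −2.8 %/decade across replicate populations;
- age–growth correlation at the size class ≈ −0.6, i.e. moderate, not
  the near-perfect determinism a large σ_tree would produce;
- ages at 27 cm spanning roughly 45–75 yr (5th–95th percentile).

The bias magnitude scales with how much of the age spread is driven by
persistent growth differences: σ_tree ≈ 0.35 (tempting from observed
between-tree variability) makes the artefact ≈ −8 %/decade and the
age–growth correlation ≈ −0.85. A single constant-mean growth process
cannot simultaneously produce a −2.8 %/decade bias under a 20-yr
recruitment SD *and* a 40–120 yr age span; we prioritised the bias
magnitude and the correlation structure. Ontogenetic (size-dependent)
mean growth, climate forcing and competition are deliberately out of
scope.

**Recruitment shapes.** Four generators: `unimodal_normal` (mean + SD),
`uniform(start, end)` (continuous regeneration; at sampling this yields
the "logistic-decline"-type age structure), `bimodal_normal` (two
cohorts + mixture weight), and `exponential_decline(start, decay)` — a
reverse-J age structure in which recruitment-year abundance decays at
`decay`/yr going back in time from the modal (most recent) year. Years
are rounded to integers.

**Stimulation.** The default multiplier is linear in time,
`m(t) = 1 + (p/100)(t − t₀)/10` for `t ≥ t₀` (a "+5 %/decade since
1975" stimulation), matching how plot-monitoring growth increases are
usually quoted. A `compound=True` variant, `m(t) = (1+p/100)^{(t−t₀)/10}`,
is exactly log-linear and is the right choice when an experiment needs
the true trend to equal a constant %/decade on the estimation scale.

**Mortality.** Annual death probability
`clamp(h·(1 + k·max(0, 1 − g5/ḡ)), 0, 1)` where `g5` is the tree's
trailing 5-yr mean increment and `ḡ` the mean over the cohort alive that
year. `k > 0` preferentially removes slow growers — enough to *generate*
predeath-type biased species for end-to-end tests. The functional form
is our own; only its direction matters, and the package never attempts
to detect or correct mortality biases (flags are analyst inputs).

## Sampling and measurement

The census keeps trees alive in the sampling year with end-of-year
diameter ≥ the threshold (default 27 cm). Growth at a class center D is
the mean increment over years whose end-of-year diameter lies in
`[D − w/2, D + w/2)`; default `w` = 4 cm. The window width is a design
guess (the field protocol it mimics does not publish one) and is
configurable; a tree so fast it jumps the window entirely contributes
its crossing-year increment. Record tables have fixed columns
(`species, tree_id, class_center_cm, growth_cm_yr, year_at_class,
age_at_class, recruitment_year`).

## Trend estimation

Trends are OLS slopes of ln(growth) on year-at-class, reported as
`100·(e^{10β} − 1)` %/decade — the only transform under which "x % per
decade" is time-consistent. Years are centered before fitting (slope
invariant). The aggregated estimator is a linear mixed model with
species-level random intercept and random year slope (statsmodels
MixedLM), fitted by ML so AICs are comparable across fixed-effect
structures; `include_age` adds age-at-class as a fixed covariate and
`standardize` divides growth by the species mean first (per-species
residual variance weighting is not available in MixedLM; standardization
is the provided alternative). Singular or non-converged fits fall back
to intercept-only random effects and finally to pooled OLS, always
flagged in the result. p-values are Wald tests; no multiple-testing
correction.

## The shuffling null

Within one species and size class, recruitment years are permuted
uniformly among trees; each tree keeps its growth and age-at-class, and
its new calendar year follows from the convention. The multiset of
recruitment years — the number distribution of recruits in time — is
preserved exactly. Each of `n_reps` (default 500) permutations is refit
with the log-linear estimator; the result stores the per-replicate
%/decade slopes, their mean and SD, a two-tailed one-sample t-test
against zero, and the mean trend line on the log scale for use by the
correction.

Shuffled trees whose new year-at-class falls after the census year are
**kept** by default: re-imposing the survivorship filter would
re-introduce the very selection the null is meant to isolate. Pass
`sampling_year=` to re-censor as a sensitivity analysis (in our
experiments the two variants differ by well under 0.1 %/decade).
Replicates with a degenerate regression are discarded; >10 % discarded
is an error. Exhaustive enumeration of all permutations (used as a test
oracle at n ≤ 6) agrees with the Monte-Carlo mean.

## Corrections

1. **Shuffled-trend subtraction.** Each record's growth is adjusted by
   the deviation of the null trend line from the species mean at its
   calendar year. The subtraction is done on the **log scale** by
   default — `ln g′ = ln g − (ln g_null(year) − mean ln g)` — because
   trends are defined and estimated on that scale; in recovery
   experiments the log variant is unbiased while the raw cm/yr variant
   (available as `scale="measurement"`, and the more literal
   "predicted minus arithmetic mean" reading) leaves a small systematic
   residual (~−0.1 %/decade) and can produce non-positive values (floored
   at ε and flagged; >5 % floored raises).
2. **Age covariate.** Adding age-at-class to the mixed model absorbs the
   age-to-calendar-year relation created by clustered recruitment.
   Caveat: this works only when ages are not themselves shaped by the
   calendar signal. A stimulation acting over the trees' whole lives
   shortens the transit of late-recruited trees, so age then *carries*
   the signal and the covariate absorbs real trend — the reason the
   canonical experiment applies stimulation only from 1975, and the
   reason our recovery tests impose the trend on the extracted records.
3. **Exclusion.** Species flagged mortality-biased (analyst input) are
   dropped from every aggregated model; species with a significantly
   positive age–calendar-year correlation at **both** size classes
   (strict `p < α`, default α = 0.05) are additionally dropped in the
   fourth model row. `build_trend_table` assembles all four rows
   (original / corrected / with-age / excluded) × (canopy / understory)
   × (full period / since-1950).

## Size-based RCS

The regional curve is the mean increment per diameter bin (default
2 cm), pooling every tree-year with the diameter taken at the start of
the year; empty bins are linearly interpolated and the curve is built
from the *sampled* trees, mirroring what an empiricist could compute.
Indices are observed/expected; the RCS trend regresses pooled ln(index)
on calendar year. Two numerical safeguards matter:

- **Diameter cap.** Bins beyond the diameter range every tree can
  traverse within the record are populated only by fast growers, which
  drags their indices toward 1 and imprints a small spurious negative
  trend (~−0.1 %/decade) even under uniform recruitment. Passing
  `max_diameter_cm` (we use the 27 cm sampling threshold) removes this
  curve-representativeness artefact.
- **Tree-clustered standard errors.** Pooled tree-years are strongly
  pseudo-replicated; naive OLS p-values reject a true-zero trend in the
  majority of replicates, while tree-clustered errors (the default when
  a `tree_id` column is present) are calibrated at the nominal rate.

With both in place, clustered recruitment plus the census filter yields
a clearly significant negative RCS trend while wide uniform recruitment
without a filter is statistically flat — the demographic bias is not an
artefact of size-class isolation.

## What the synthetic data do and do not show

The generator reproduces the features the bias mechanism needs:
persistent growth ranking, autocorrelated annual variation, controlled
recruitment distributions, census survivorship, and (optionally)
growth-dependent mortality. It omits ontogenetic growth curves, climate
signals, stand dynamics (e.g. post-disturbance competition, which in
real data can push apparent trends below the shuffled null), crossdating
error, and measurement noise. Passing tests therefore demonstrate the
*logic* of the bias and its corrections, not the magnitude of any trend
in real forests; real reanalyses should treat mortality-bias flags and
recruitment-shape classifications as external expert input, exactly as
the API does.

## Problem sizes and determinism

Default experiment sizes (500 populations × 200 trees for the headline
artefact; 100–200 replicates elsewhere; 400–500 shuffle replicates per
null) keep every experiment in seconds-to-minutes on one CPU while
holding Monte-Carlo error well below the effects measured. All
randomness flows from a single seed through `numpy` `SeedSequence`
spawning (one substream per species and per tree), so identical
(configuration, seed) pairs reproduce byte-identical outputs, including
the full pipeline bundle.
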