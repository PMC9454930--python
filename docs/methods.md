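# Methods

## Model structure

`lcscreen` is a discrete-time Markov cohort model with five health states
— healthy, localized lung cancer (LC), disseminated LC, false-positive
screen, dead — an annual cycle, and a lifetime horizon ending at age 110,
where the life table closes with a death probability of one.  Two
strategies are compared on identical inputs: usual care (the surveillance
programme without screening) and organized LDCT screening at a 1- or
2-year interval from the start age (50, 55 or 60) for as long as the
subject is healthy, with no upper age cap.

Within a cycle, events from the healthy state are ordered and mutually
exclusive: background death first (probability `q(age, sex)` from the
life table), then LC diagnosis, then — among subjects neither dead nor
diagnosed — a false-positive screen.  Each transition row therefore sums
to one by construction, and the healthy→dead probability is identical in
both arms, encoding the assumption that screening does not change the
life expectancy of people who never receive an LC diagnosis.

Diagnosed states are exit-only-to-death.  The heterogeneous courses after
a localized diagnosis (cure, progression, death) are collapsed into one
stage-specific death hazard ratio applied to background survival,
`p_death = 1 − (1 − q)^HR`, with HR 2.68 (localized) and 8.38
(disseminated).  A rate-scaling alternative `1 − exp(−HR·q)` is available
(`lc_death_prob(..., method="rate-scaling")`); the two differ by well
under 1% at the probabilities involved.  There is no explicit
localized→disseminated progression and no cure return to healthy; both
are absorbed into the hazard ratios.

A false positive occupies its state for one cycle, accrues the work-up
cost (2110 €) and, in the base case, no utility loss (utility 1.000);
scenario analyses apply a 0.10 disutility for that cycle.  During the
work-up year the subject still faces background death and the same LC
incidence as a healthy subject.  This last point is a deliberate design
choice: if the false-positive state suspended cancer risk for a year, a
high false-positive rate would mechanically *reduce* cancer incidence in
the screening arm, and the 23.3% false-positive scenario would lower the
ICER instead of raising it — the opposite of what a more aggressive
work-up algorithm does in reality.

## Incidence inputs

LC incidence enters as stratum- and age-band-specific rates per 1000
person-years (whole cohort 2.30‰; high-exposure smokers 7.07‰; asbestosis
5.00‰; etc.), converted per cycle as `p = 1 − exp(−rate)`.  Bands are
<60, 60–75 and >75 years; bands without a published estimate (elderly
current smokers, asbestosis outside 60–75) fall back to the 60–75 band,
and the affected bands are reported by `SubgroupSpec.fallback_bands`
rather than silently substituted.  Under annual screening, detection is
multiplied by the overdiagnosis ratio 1.13 and split 70.2/29.8 between
localized and disseminated; under usual care the split is 18.1/81.9.

The base-case cohort trace starts every subject at the screening start
age (sex blended 94.8% male at the subject level).  The published
bookkeeping requires this: roughly 4993 false positives at 1.2% per
screen imply ≈29 screens — hence ≈29 healthy person-years — per subject,
which is only attainable if the whole cohort enters at 55, not at its
mixed entry ages.  Mixed-age runs remain available by blending
per-profile traces (`CohortTrace.blend`), which is exact because the
cohort model is linear in its start distribution.

## Biennial screening

Biennial screening keeps the annual cycle but screens (and accrues
screening costs and false-positive risk) every second year.  Diagnoses
are split into a screen-detected compartment carrying the screening stage
fractions and an interval-cancer compartment carrying the usual-care
stage fractions, with weights r/(r+1) and 1/(r+1) from the
screen-detected : interval ratio r = 2.8 (from 7.69 vs 2.76 cancers per
1000 screens in two-yearly screening).  Total biennial detection equals
the underlying incidence times `biennial_overdiagnosis`, default 1.0 —
i.e. no overdiagnosis excess.  That default follows the published
biennial outcome tables, in which the biennial intervention arm's total
diagnoses equal the usual-care arm's exactly (no 13% excess), indicating
that the overdiagnosis multiplier was treated as an annual-frequency
phenomenon.  An alternative `capped_yield` convention implements the
literal reading — screen-detected compartment scaled by the
overdiagnosis ratio and a biennial detection factor (1.5), capped so the
biennial arm never detects more than the annual arm — and is selectable
per strategy; the published MILD-derived detection-factor footnote is
arithmetically ambiguous, so the factor is exposed as a config knob
rather than hard-wired.

## Costs, QALYs, discounting

Per cycle: healthy occupants accrue the usual-care annual cost (26 €,
both arms); each screen performed costs 189 €; each new false positive
2110 €; each entry into the localized state incurs the 13,390 € surgical
cost once; localized occupancy accrues the 19,057 € post-surgical amount
and disseminated occupancy the 33,132 € amount.  The last two are
printed as per-2-year figures; the model charges
`amount × cycle_fraction` per year of occupancy with
`postsurgical_cycle_fraction = 1.0` and
`disseminated_cycle_fraction = 0.5` by default.  This asymmetric default
is a calibration decision: charging the post-surgical amount in full
every cycle (and the disseminated amount annualized) reproduces all four
published per-arm discounted cost totals to within about 10%, whereas
annualizing both (`0.5/0.5`) under-predicts the intervention arm's total
cost by nearly 30%.  Both fractions are plain config parameters, so the
strict per-2-year reading is one line away.

QALYs weight state occupancy by utilities (healthy 1.0 — not printed
with the utility set but required for the ≈17.7 discounted QALY totals to
be attainable — localized 0.825, disseminated 0.573, false positive
1.000).  Costs and QALYs are discounted at the same 3% annual rate
(scenarios: 2%, 6%), with cycle t (t = 0, 1, …) discounted by
(1+r)^−t — the first model year undiscounted.  No half-cycle correction
is applied; the occupancy reached during a cycle accrues that full
cycle's cost and utility.  Dominance (screening cheaper and more
effective, or dearer and less effective) is labelled, and the ICER is
flagged undefined when |ΔQ| < 1e−9 rather than returned as an arbitrary
ratio.

## Parameter uncertainty

Each uncertain parameter carries a deterministic value and low/high
parametric bounds, read as a central 95% interval: SE = (high − low)/3.92.
Costs are gamma (method-of-moments shape (m/SE)², scale SE²/m), utilities
beta (moment inversion; infeasible interior moments raise an error naming
the parameter, and a boundary mean of exactly 0 or 1 degenerates to a
point mass — the false-positive utility is printed as exactly 1.000),
stage fractions normal with each arm's pair renormalized to sum to one
after drawing.  Asymmetric bounds (the disseminated cost's 29,357/34,305
around 33,132, which are age-group variants rather than symmetric errors)
are used only through the full-span SE; no shifted or skewed distribution
is fitted.  Sampled costs are truncated at zero and utilities clipped to
[0, 1].

The base PSA (default 10,000 draws) redraws costs, utilities and stage
fractions; the overdiagnosis ratio, false-positive rate, death hazard
ratios and biennial constants stay fixed (their printed bounds are
dashes) and move only in scenario/tornado analyses.  The point estimate
is always the all-deterministic run, never the draw mean.  Intervals are
reported under two conventions: min–max of the draws (the convention the
published uncertainty intervals describe) and 2.5/97.5 percentiles.
Draws with non-positive QALY increments are retained and counted, not
dropped.  The tornado analysis sweeps each parameter (stage-split pairs
jointly and complementarily) to its bounds with everything else
deterministic, plus the structural one-ways: false-positive rate 0.012 →
0.233 (NLST-style work-up), overdiagnosis 1.03 → 1.23, discount 2% → 6%;
bars are sorted by ICER span.

## Background mortality

The published analysis used the INED 2019 French period life table,
which is not reproduced in the source material.  The package bundles a
*synthetic* substitute (`life_table_fr2019_synthetic.csv`): a
Gompertz–Makeham hazard μ(x) = A + B·e^{Cx} per sex with C = 0.105,
Makeham terms A = 8×10⁻⁴ (men) and 3×10⁻⁴ (women), and B solved so that
period life expectancy at 60 is 23.0 years for men and 27.5 for women
(French 2019 values).  The table covers integer ages 50–110, is forced
monotone, and closes with q(110) = 1.  Any table in the same
`age,sex,qx` text schema can be loaded in its place.

## Synthetic cohort

`generate_cohort` draws subjects independently from the published
marginal composition (94.8% male; entry-age bands 23.4%/73.8%/2.8%, ages
uniform within bands, the lower band starting at 55 because younger
subjects enter the model at the screening start age; smoking
30/61.5/8.5% never/former/current among subjects with known status;
exposure 7.5/68.0/24.5%).  Pleural-plaque (18%) and asbestosis (3%)
prevalences are assumed at surveillance-cohort-typical values because no
marginal is published; they affect only subgroup sizes, never incidence
rates, which are stratum inputs.  Attribute correlations (plaques with
exposure level, smoking with sex) are deliberately not modelled: the
decision model consumes stratum rates, not individual records, so
passing cohort tests demonstrates rate recovery and composition, not
realistic joint structure.  Missing smoking status (≈31% of the real
cohort) is not emulated; generated cohorts are complete.

`simulate_incidence` follows each subject under a piecewise-constant
hazard (the stratum's age-band rates, switching as the subject ages
through 60 and 75) for a 17-year window, drawing the diagnosis time by
inversion of the cumulative hazard, which yields exact person-years.
Rates are estimated as events/PY with exact (Garwood) Poisson intervals.
Because of the band structure and ageing, the estimand is the cohort's
person-year-weighted band rate (`expected_rate`), which can differ by a
few percent from the published all-ages figure; coverage tests target the
estimand.  Strata passed together must partition the cohort — overlap or
an unmatched subject is an error listing the subject's attributes —
mirroring how each subgroup scenario filters the cohort with its own
predicate.  Background mortality is not simulated here; the window is
short and the published rates are themselves net of competing risks.

## Reproduction scope and known deviations

With the bundled life table the model reproduces, at the published
parameter values: the usual-care stage split (18.1% localized, exact by
construction), the intervention/usual diagnosis ratio (1.13), the
false-positive and localized-diagnosis counts (within ~12%, the life
table accounting for most of the gap — the published bookkeeping implies
≈29 healthy years per subject against 27.3 under our table), the
per-arm discounted cost totals and the incremental cost of annual
screening (within ~3%), and the biennial QALY gain (within ~8%).

The published *QALY increments* for the annual strategies are not
reproducible under any configuration of this model class, and we left
them unmatched rather than distort the model: the per-case QALY gain
implied by the published increments and event counts (≈2.0 discounted
QALYs per stage-shifted case) is smaller than the survival difference
alone that follows from the published hazard ratios and the state
durations embedded in the published cost totals (≥4 discounted years).
Since ΔQ sits in the ICER denominator, our annual-strategy ICERs land
~35–40% below the published point values while the cost side matches.
Similarly, the published PSA intervals are several times wider than the
printed low/high parameter bounds can generate (the published text drew
the death hazard ratios from distributions whose spread is not printed;
we keep them fixed in the base PSA rather than invent one), so the
acceptability fraction at 50,000 €/QALY evaluates to ≈1.0 here against a
published 58.5%.  All of these comparisons are recomputed, not asserted,
by `scripts/acceptance.py` and `tests/test_acceptance.py`.

## Problem sizes and determinism

Default runs use the full 14,218-subject scale (the trace is a cohort
model, so size enters only as a scale factor), 10,000 PSA draws, and
200-replicate incidence-recovery checks on the full cohort; the whole
test suite runs in a few minutes on one core.  All randomness flows
through numpy Generators seeded from user-supplied integers; reruns are
bit-identical, and the CLI writes input hashes and the seed into every
output bundle.

## Limitations

Beyond the deviations above: no microsimulation of tumour growth or
nodule management (the false-positive rate is the only work-up
parameter); no radiation-induced harms; no indirect or societal costs;
no exposure-duration or pack-year dose–response; no mesothelioma; utility
values are not French-specific; overdiagnosed cancers are treated as
ordinary localized cancers (mortality and costs included), which is
conservative against screening; and background mortality in the healthy
state retains population LC mortality (no cause deletion), a second-order
double count shared by the published analysis.
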