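# lcscreen

Markov cohort cost-effectiveness model of organized low-dose CT (LDCT)
lung-cancer screening for people with occupational asbestos exposure.

Asbestos remains the leading occupational lung-cancer risk factor, and
post-exposure surveillance programmes follow large cohorts of retired
exposed workers.  Whether those cohorts should be offered organized LDCT
screening — and on what eligibility criteria — is an open health-policy
question: trial evidence (NLST, NELSON, MILD) covers heavy smokers, not
occupational exposure.  `lcscreen` implements a five-state Markov cohort
model that compares usual care (no screening) against annual or biennial
LDCT screening for an asbestos-surveillance cohort of 14,218 subjects
(94.8% male), using published stratum-specific lung-cancer incidence
rates, trial-based screening effects, French cost data and literature
utilities.  It is written for health-economics researchers who want to
reproduce, stress or extend that analysis.

## Model

States: healthy, localized lung cancer (stage I–II), disseminated lung
cancer (stage III–IV), false-positive screen, dead.  Cycle length 1 year,
horizon to age 110.  For a subject aged *a* with stratum incidence rate
*λ(a)* (per person-year) and background death probability *q(a, sex)*:

- annual cancer probability `p = 1 − exp(−λ)`, multiplied under annual
  screening by the overdiagnosis ratio 1.13;
- stage split at diagnosis: 18.1% / 81.9% localized/disseminated under
  usual care, 70.2% / 29.8% under annual screening (the stage shift);
  biennial screening mixes the two splits at the screen-detected :
  interval-cancer ratio 2.8 : 1;
- death from a cancer state: `1 − (1 − q)^HR` with HR 2.68 (localized)
  and 8.38 (disseminated) applied to background survival;
- false positives occur at 1.2% per screen, cost a work-up, and return to
  the healthy state after one cycle;
- costs (screen 189 €/round, localized surgery 13,390 € plus follow-up,
  disseminated care 33,132 €/2 years, FP work-up 2110 €) and utilities
  (healthy 1.0, localized 0.825, disseminated 0.573) accrue per cycle and
  are discounted at 3%/year.

Outputs are incremental cost ΔC, incremental QALYs ΔQ and the ICER
ΔC/ΔQ (€/QALY).  Probabilistic sensitivity analysis redraws costs
(gamma), utilities (beta) and stage fractions (normal, renormalized) from
their published low/high bounds; one-way tornado sweeps and a
population × start-age × interval scenario grid cover the subgroup
analyses.  Background mortality comes from a bundled synthetic
Gompertz–Makeham period life table calibrated to French 2019 life
expectancies (e60 = 23.0 y men / 27.5 y women); any table in the same
`age,sex,qx` schema can be dropped in.  See `docs/methods.md` for
conventions, calibration choices and known limitations.

## Worked example

```python
from lcscreen import LifeTable, default_parameters
from lcscreen.psa import ScenarioSpec, run_cea

params = default_parameters()        # bundled base-case inputs
life = LifeTable.bundled()

res = run_cea(ScenarioSpec("total_population", start_age=55, interval=1),
              params, life)
print(f"dC = {res.delta_cost:.0f} EUR, dQ = {res.delta_qalys:.4f} QALY, "
      f"ICER = {res.icer:,.0f} EUR/QALY")
print(f"false positives: {res.events['false_positives']:.0f} per 14,218")
```

prints

```
dC = 6785 EUR, dQ = 0.0622 QALY, ICER = 109,049 EUR/QALY
false positives: 4375 per 14,218
```

i.e. lifetime annual screening of the whole cohort costs about 6800 € per
person more than usual care, buys 0.06 discounted QALYs, and is therefore
far above common willingness-to-pay thresholds — whereas the same model
restricted to smokers with high asbestos exposure under biennial
screening (`ScenarioSpec("high_exposure_smokers", 55, 2)`) yields an ICER
of about 31,000 €/QALY, inside the usually accepted range.

The same analyses are available from a shell:

```sh
lcscreen --seed 1 --out-dir out basecase     # 4-strategy summary table
lcscreen --seed 1 --out-dir out psa          # 10,000-draw PSA + CEAC
lcscreen --seed 1 --out-dir out tornado      # one-way sensitivity sweeps
lcscreen --seed 1 --out-dir out scenarios    # subgroup ICER grid
lcscreen --seed 1 --out-dir out synthcohort  # synthetic cohort table
```

Every output carries the seed and a manifest of input hashes; reruns with
the same config are bit-identical.

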