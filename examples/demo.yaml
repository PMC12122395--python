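# Demo run: synthetic cohort with a dichotomous ("step") prescribing policy
# in the ICU only — the configuration under which the 0.25 ng/mL ICU grid
# cells should show a genuine discontinuity.
outdir: results_demo
seed: 42
generator:
  n_encounters: 10000
  seed: 42
  reporting_decimals: 2
  loc_probs: {floor: 0.50, stepdown: 0.17, icu: 0.33}
  exclusion_rates:
    late_pct: 0.12
    ed_discharge: 0.10
    obstetrics: 0.04
    repeat_encounter: 0.05
  policy:
    floor:    {kind: continuous, intercept: 1.8293, slope: 0.5936}
    stepdown: {kind: continuous, intercept: 1.8293, slope: 0.5936}
    icu:      {kind: step, intercept: 1.8293, slope: 0.5936,
               jump: 1.2, step_location: 0.25}
cutpoints: [0.1, 0.25, 0.5]
bandwidths: [0.03, 0.05, 0.10]
strata: [all, floor, stepdown, icu]
alpha: 0.05
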