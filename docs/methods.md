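# Methods

`pctrda` asks whether prescribers treat procalcitonin (PCT) as a
dichotomous or a continuous test, by estimating discontinuities in the
probability of a full antibiotic course at the classical PCT cut-points.
This note records the models, the defaults and why they are what they are,
and what the synthetic world does and does not establish.

## The estimand and the discontinuity model

Let X be the first reported PCT of an encounter (ng/mL), Y the binary
outcome "received a full antibiotic course", and c a pre-specified
cut-point (0.1, 0.25 or 0.5 ng/mL). PCT assays carry 10–30% analytical and
intra-individual variability, so values just below and just above c are
plausibly exchangeable; a jump in P(Y=1) at c then identifies a causal
effect of the cut-point on the decision (sharp design: T = 1{X ≥ c} by
construction).

Within a uniform-kernel window [c−h, c+h) we fit a logit-link GLM on
{1, T, X−c, T·(X−c)} and report

* **jump** = expit(β₀+β₁) − expit(β₀), the discontinuity in probability at
  X→c, with a delta-method Wald CI, and the Wald p-value of β₁;
* **odds ratio** = the raw within-window 2×2 OR (full-course odds above vs
  below c) with a log-scale Wald CI — the descriptive counterpart shown
  alongside the model.

Design choices, since binary-outcome sharp-RDD practice leaves them open:

* *Link and order.* Local-linear on each side of c with a
  treatment×running-variable interaction: the interaction absorbs any
  smooth prescribing gradient so that only a genuine discontinuity loads on
  T; logit link because the outcome is binary and windows can sit at
  extreme prevalences.
* *Side of the boundary.* X = c counts as "above": labs flag values at or
  over a threshold as abnormal, and with 2-decimal reporting the bins
  0.20–0.24 / 0.25–0.29 partition the 0.25 ± 0.05 window exactly.
* *Bandwidths.* Pre-specified, not data-driven: h = 0.05 ng/mL at c = 0.1
  and 0.25, h = 0.10 at c = 0.5 (relative assay variability grows with the
  level), plus a sensitivity grid h ∈ {0.03, 0.05, 0.10} for every
  cut-point and level-of-care stratum (36 cells). No multiplicity
  adjustment by default — the grid is read against its chance expectation —
  with an optional Benjamini–Hochberg column (`bh_adjust`).
* *Degenerate and unstable cells.* An empty window side yields a flagged
  degenerate result (never an exception, so grids always complete). An
  empty 2×2 cell gets the Haldane 0.5 correction (`haldane` flag). If the
  GLM cannot be fit stably (complete separation; detected by non-finite or
  huge coefficient standard errors), the cell falls back to the difference
  in proportions with a score CI and a two-proportion p (`separation`
  flag). The local-linear jump test has roughly 4× the variance of a
  pooled two-proportion comparison (boundary extrapolation), which is the
  price of slope robustness; its size is nominal (~0.05) under smooth
  policies.

## Course classification

Full course = (a) antibiotics on ≥4 distinct calendar days within some
window of 5 consecutive calendar days during the stay, or (b) an antibiotic
discharge prescription with ≥4 days supplied, or (c) a discharge
prescription flagged as continuing the inpatient regimen with distinct
inpatient antibiotic days + days supplied ≥ 4. Otherwise *partial* if any
antibiotic exposure exists, *none* if not; the analysis outcome pools
partial and none. Conventions: a calendar day is the civil date of the
administration timestamp (no timezone conversion); multiple doses on one
day count once; rule precedence a > b > c is recorded but only the
category matters downstream. Rule (a) is implemented as "four sorted
distinct antibiotic days spanning ≤4 days" and verified against an
exhaustive window-enumeration oracle; regimen identity for rule (c) is
carried by an explicit flag rather than inferred from drug names.

## Eligibility filter

Exclusions are attributed in a fixed order (unparseable timestamps, age
< 18, obstetrics/pregnancy, repeat encounter, PCT drawn more than 48 h —
strictly — after the first antibiotic dose, ED discharge) so that each
dropped row is counted exactly once and raw = eligible + Σ excluded always
holds. The 48 h rule applies only when an antibiotic dose exists. The order
itself is a reporting convention; different orders redistribute counts
among rules but select the same cohort.

## The synthetic world

The generator emulates the statistical structure the analysis needs, not a
hospital:

* **PCT**: a two-component lognormal mixture, weights/parameters
  (0.4395, μ=−0.0766, σ=1.4642) and (0.5605, μ=−2.4883, σ=0.9498), rounded
  to 2 decimals (lab reporting precision). Policy evaluation clamps PCT at
  a 0.02 ng/mL floor before taking logs (assay-floor values in user data
  would otherwise give −∞ log-odds).
* **Prescribing policy**: P(full | X) per level of care. Default:
  continuous, logit P = 1.8293 + 0.5936·ln X in every stratum. The mixture
  and policy were calibrated jointly, once, by numerical integration
  against published cohort anchors — 68.9% full-course rate, conditional
  PCT medians 0.29 / 0.08 ng/mL with IQRs 0.1–1.24 / 0.04–0.19, 39.1% /
  10.2% above 0.5 ng/mL, decision AUC ≈ 0.72 — and then frozen. `step` and
  `mixture` policies express the dichotomous and mixed-provider hypotheses.
* **Records**: for each latent decision the generator emits administration
  events and discharge prescriptions through a qualifying pattern chosen
  uniformly among the feasible course rules (full), a pattern provably
  failing all rules (partial), or no antibiotic records (none), plus
  non-antibiotic noise records — so classification of the emitted records
  recovers the latent decision exactly (round-trip guarantee, tested at
  100% over ≥10⁴ encounters). Non-full decisions split partial/none by a
  configurable Bernoulli (default 0.5); the analysis pools them anyway.
* **Stays**: length of stay lognormal with median 5 days (the analysis
  only needs window logic over stay dates, not realistic LOS), admissions
  uniform over a two-year span from a fixed epoch; ages normal(61.4, 16.4)
  truncated at 18; level of care multinomial (floor 0.50 / step-down 0.17 /
  ICU 0.33, the ICU share back-computed from published strata sizes).
* **Injected exclusions**: mutually exclusive per encounter, rates
  late-PCT 0.12, ED discharge 0.10, obstetrics 0.04, repeat encounter 0.05
  (summing to ≈31%, the published overall exclusion fraction; the per-rule
  split is unpublished and therefore arbitrary). Injection is constructed
  to be exactly recoverable: late-PCT encounters are guaranteed an
  antibiotic dose and get PCT re-timed past dose + 48 h; repeat encounters
  re-use the patient of a clean host and start strictly after its
  discharge.

What the synthetic world does **not** emulate: diagnosis, comorbidity,
disposition and mortality are opaque labels independent of everything;
level of care is independent of PCT (the real-world ICU/decision
association is absent, so stratified AUCs coincide up to noise);
PCT trajectories (only a first value exists); drug identities. A green
test therefore establishes the *operating characteristics of the methods*
— classifier correctness, filter audit algebra, test size/power, AUC
identities — not any clinical claim.

## Numerical conventions

Rounding is numpy round-half-to-even. ROC curves use the "score ≥
threshold" sweep with ±∞ sentinels; AUC equals the normalized Mann–Whitney
U with ties half-weighted, exactly. ROC orientation is fixed (higher PCT →
full course); AUC < 0.5 is reported as-is. The "visual inflection" read of
a ROC curve is quantified as the change in chord slope between adjacent
annotated cut-points — an exploratory descriptor only. Welch's t uses
Welch–Satterthwaite degrees of freedom; Fisher's exact test (two-sided,
point-probability rule) replaces chi-squared in 2×2 tables with any
expected cell < 5, and the test chosen is recorded per variable. First-PCT
selection takes the chronologically earliest result, ties broken by input
order. All randomness flows through one `numpy.random.Generator` per run;
identical config + seed gives byte-identical CSVs.

## Known limitations

* The partial/none boundary beyond "any antibiotic exposure" is this
  package's reading; institutional definitions may differ.
* Whether a discharge prescription's days supplied counts the discharge
  day is taken at face value from the data.
* The exclusion-attribution order is a convention (counts per rule are
  order-dependent); only the resulting cohort is order-invariant.
* The local-linear logit jump test is underpowered relative to a pooled
  2×2 comparison at equal n (variance price of slope robustness); grid
  cells at narrow bandwidths in small strata are frequently flagged
  degenerate or separated, mirroring the small-cell reality of this
  design.
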