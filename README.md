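# vtecea

A lifetime Markov cohort cost-effectiveness model of **extended
anticoagulation after venous thromboembolism (VTE)**: continued apixaban
2.5 mg twice daily versus stopping anticoagulation after the initial
6-month treatment, for a Dutch-type cohort (entry age 56.9 years, 58%
male, 66% index deep-vein thrombosis / 34% index pulmonary embolism).

The package is aimed at health-economic modellers and methods researchers
who need a fully scripted, testable state-transition model rather than a
spreadsheet: every transition probability, conversion rule and accounting
convention is code with unit tests, and the stochastic analyses are
reproducible from a single seed.

## The model

A closed cohort moves through 12 health states in 3-month cycles until
death or age 100: index DVT, index PE, on-treatment without event,
recurrent DVT, recurrent PE, major bleeding (non-intracranial),
intracranial bleed, clinically relevant non-major bleeding (CRNMB),
chronic thromboembolic pulmonary hypertension (CTEPH), off-treatment
without event, VTE-related death, and death from other causes. Severe
postthrombotic syndrome (PTS) runs as a background process over patients
with DVT history. Event states are one-cycle tunnels.

Per cycle, independent cause-specific probabilities are composed on the
survival scale and allocated proportionally to their hazards,

&nbsp;&nbsp;&nbsp;&nbsp;p_any = 1 − ∏ᵢ (1 − pᵢ),&nbsp;&nbsp;
share_i = p_any · λᵢ / Σλ,&nbsp;&nbsp; λᵢ = −log(1 − pᵢ).

Recurrence risk is time-dependent: trial-derived interval risks for months
6–18 after the index event, then a piecewise-constant hazard from a
published post-cessation cumulative-incidence curve, scaled on the rate
scale by the trial treatment effect
log(1 − cum_treated) / log(1 − cum_untreated) ≈ 0.174 for patients still
anticoagulated. Bleeding risks rise with age by a per-decade factor of
1.97 applied on the rate scale in whole elapsed decades. Background
mortality comes from a sex-mixed period life table with a mortality hazard
ratio of 4.41 for VTE patients (extra factors after intracranial bleed and
CTEPH).

Outcomes are discounted costs (4%/year, societal or healthcare-payer
perspective) and QALYs (1.5%/year), combined into the incremental
cost-effectiveness ratio ICER = ΔC/ΔE. Uncertainty propagates through a
2,000-iteration probabilistic sensitivity analysis (beta/gamma/lognormal/
Dirichlet distributions matched to each estimate's 95% CI) and one-way
sweeps for the tornado diagram.

**Costs and utilities shipped with the package are flagged synthetic
placeholders** — the authoritative unit values live in supplementary
material of the source publications and must be transcribed by the user to
reproduce published euro amounts. Transition probabilities, hazard ratios
and the validation harness are complete as published.

## Worked example

Replicate the extension trial (apixaban N=804 vs no treatment N=829,
12 months = four cycles) from the packaged transition probabilities:

```bash
vtecea validate --out out/
```

```
                outcome  trial_apixaban  trial_no_treatment  trial_rr  model_apixaban  model_no_treatment  model_apixaban_rounded  model_no_treatment_rounded  model_rr
recurrent_vte_and_death              14                  73      0.19       12.658738           71.620912                      13                          72      0.18
         major_bleeding               2                   4      0.49        1.902162            3.861577                       2                           4      0.51
                  crnmb              25                  19      1.29       23.741932           18.674535                      24                          19      1.31
        all_cause_death              32                  96      0.33       18.722847           26.443112                      19                          26      0.73
```

Reading: over 12 months the model predicts 13 recurrent VTE events or
VTE-related deaths among 804 extended-treatment patients versus 72 among
829 untreated patients (relative risk 0.18 on unrounded counts) — a
five-fold reduction in recurrence at the price of more CRNMB (24 vs 19)
and no major-bleeding excess (2 vs 4). All-cause death depends on the
background life table (here the synthetic one) and is shown for context
only.

A lifetime base-case run with the placeholder economics:

```bash
vtecea run --out out/
# base: dC=3,572 EUR, dE=0.316 QALY, ICER=11,301 EUR/QALY (trade-off)
```

Per 1,000 patients over lifetime, extended treatment costs ~€3.6k more per
patient and yields ~0.32 additional QALYs — about €11k per QALY gained
*under the placeholder registry*. `out/summary.json` lists every
placeholder parameter that went into those euros; replace them with
transcribed values (`--params your_file.yaml`) for authoritative results.

Other commands: `vtecea psa` (CE plane + CEAC), `vtecea tornado` (one-way
sweeps), `vtecea scenario` (payer perspective and equalised-bleeding-risk
variants).

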