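# Base-case parameter file for the extended-VTE-treatment Markov model.
#
# Transition probabilities, hazard ratios and distribution families are the
# published base-case values for the extended treatment phase (apixaban
# 2.5 mg twice daily vs no treatment).  Period bases: the per-interval
# recurrence risks are per 3-month cycle; bleeding and discontinuation risks
# are 12-month risks rescaled to the cycle at run time; the severe-PTS risk
# is a 5-year risk.
#
# COSTS AND UTILITIES BELOW ARE SYNTHETIC PLACEHOLDERS (provenance:
# placeholder).  The authoritative unit values live in supplementary
# material not reproduced here; transcribe them into a copy of this file to
# reproduce published economic results.  Placeholders are order-of-magnitude
# plausible for Dutch 2015 tariffs only.

model:
  cycle_months: 3
  start_age: 56.9
  male_fraction: 0.58
  index_pe_fraction: 0.34
  max_age: 100
  discount_rate_costs: 0.04
  discount_rate_effects: 0.015
  late_bleeding_source: arm_specific

transition_probabilities:
  recurrence:
    apixaban:
      - {interval: "6-9",   mean: 0.0048, ci_low: 0.0001, ci_high: 0.0094, distribution: beta, basis_months: 3}
      - {interval: "9-12",  mean: 0.0059, ci_low: 0.0007, ci_high: 0.0111, distribution: beta, basis_months: 3}
      - {interval: "12-15", mean: 0.0012, ci_low: 0.0000, ci_high: 0.0035, distribution: beta, basis_months: 3}
      - {interval: "15-18", mean: 0.0036, ci_low: 0.0000, ci_high: 0.0076, distribution: beta, basis_months: 3}
    no_treatment:
      - {interval: "6-9",   mean: 0.0277, ci_low: 0.0166, ci_high: 0.0389, distribution: beta, basis_months: 3}
      - {interval: "9-12",  mean: 0.0265, ci_low: 0.0156, ci_high: 0.0375, distribution: beta, basis_months: 3}
      - {interval: "12-15", mean: 0.0217, ci_low: 0.0118, ci_high: 0.0316, distribution: beta, basis_months: 3}
      - {interval: "15-18", mean: 0.0121, ci_low: 0.0046, ci_high: 0.0195, distribution: beta, basis_months: 3}
  event_split:            # distribution of recurrent events (Dirichlet, ESS 101)
    vte_death:     {mean: 0.1188}
    recurrent_pe:  {mean: 0.2475}
    recurrent_dvt: {mean: 0.6337}
  # Cumulative incidence of recurrence after treatment cessation.  The
  # published table prints 0.0110 for the first-year knot; the bracketing CI
  # (0.0950-0.1250) and the cited 11% first-year recurrence identify this as
  # a typo for 0.110, stored corrected here.
  post_cessation_curve:
    - {time_years: 1,  mean: 0.110, ci_low: 0.0950, ci_high: 0.1250, distribution: beta}
    - {time_years: 3,  mean: 0.196, ci_low: 0.1750, ci_high: 0.2170, distribution: beta}
    - {time_years: 5,  mean: 0.291, ci_low: 0.2630, ci_high: 0.3190, distribution: beta}
    - {time_years: 10, mean: 0.399, ci_low: 0.3540, ci_high: 0.4440, distribution: beta}
  mb:                     # major bleeding, 12-month risks beyond first 6-month treatment
    apixaban:     {mean: 0.0024, ci_low: 0.0000, ci_high: 0.0057, distribution: beta, basis_months: 12}
    no_treatment: {mean: 0.0048, ci_low: 0.0001, ci_high: 0.0096, distribution: beta, basis_months: 12}
  crnmb:                  # clinically relevant nonmajor bleeding, 12-month risks
    apixaban:     {mean: 0.0300, ci_low: 0.0182, ci_high: 0.0412, distribution: beta, basis_months: 12}
    no_treatment: {mean: 0.0230, ci_low: 0.0128, ci_high: 0.0332, distribution: beta, basis_months: 12}
  fatal_mb_fraction:    {mean: 0.1346, ci_low: 0.1128, ci_high: 0.1580, distribution: beta}
  nonfatal_ic_fraction: {mean: 0.1397, ci_low: 0.1160, ci_high: 0.1652, distribution: beta}
  bleeding_age_factor:  {mean: 1.970, ci_low: 1.7900, ci_high: 2.1600, distribution: lognormal}
  interruption_mb:      {mean: 0.4727, ci_low: 0.3434, ci_high: 0.6039, distribution: beta}
  interruption_mb_days: 14
  interruption_crnmb:   {mean: 1.0, ci_low: 1.0, ci_high: 1.0, distribution: fixed}
  interruption_crnmb_days: 2
  other_discontinuation: {mean: 0.0667, ci_low: 0.0498, ci_high: 0.0835, distribution: beta, basis_months: 12}
  cteph_annual:          {mean: 0.0125, ci_low: 0.0003, ci_high: 0.0246, distribution: beta, basis_months: 12}
  pts_5yr:               {mean: 0.0812, ci_low: 0.0500, ci_high: 0.1000, distribution: beta, basis_months: 60}
  mortality_hr:
    index_dvt:   {mean: 4.41, ci_low: 3.63, ci_high: 5.36, distribution: gamma}
    index_pe:    {mean: 4.41, ci_low: 3.63, ci_high: 5.36, distribution: gamma}
    post_ic:     {mean: 2.60, ci_low: 2.20, ci_high: 5.60, distribution: gamma}
    post_cteph:  {mean: 1.30, ci_low: 0.98, ci_high: 1.73, distribution: gamma}

# --------------------------------------------------------------------------
# SYNTHETIC PLACEHOLDER registries (euros, 2015 price year).
# --------------------------------------------------------------------------
costs:
  event:                       # one-off acute cost at occurrence
    recurrent_dvt:            {value: 400,   provenance: placeholder}
    recurrent_pe:             {value: 2200,  provenance: placeholder}
    vte_death:                {value: 500,   provenance: placeholder}
    fatal_mb:                 {value: 18000, provenance: placeholder}
    nonfatal_ic_mb:           {value: 26000, provenance: placeholder}
    nonfatal_extracranial_mb: {value: 4000,  provenance: placeholder}
    crnmb:                    {value: 30,    provenance: placeholder}
    cteph_onset:              {value: 5000,  provenance: placeholder}
  per_cycle:                   # recurring 3-monthly state cost
    cteph_maintenance:        {value: 625,   provenance: placeholder}
    pts:                      {value: 25,    provenance: placeholder}
    inr_monitoring_visit:     {value: 11,    provenance: placeholder}
  drug_per_day:                # drug + administration per treated day
    apixaban_extended:        {value: 2.10,  provenance: placeholder}
    apixaban_initial:         {value: 4.20,  provenance: placeholder}
    vka:                      {value: 0.08,  provenance: placeholder}
    lmwh:                     {value: 9.00,  provenance: placeholder}
  travel_per_visit: 7.0        # mean one-way 7-km trip tariff
  travel_provenance: placeholder
  inr_visits_per_cycle: 3.25   # ~13 INR checks per VKA-treated year
  productivity:                # friction-cost inputs
    hourly_wage:              {value: 34.75, provenance: placeholder}
    employment_probability:   {value: 0.65,  provenance: placeholder}
    friction_period_days:     {value: 85,    provenance: placeholder}
    workday_hours:            {value: 8,     provenance: placeholder}
  absence_days:                # work days lost per event
    recurrent_dvt:            {value: 10,  provenance: placeholder}
    recurrent_pe:             {value: 20,  provenance: placeholder}
    vte_death:                {value: 85,  provenance: placeholder}
    fatal_mb:                 {value: 85,  provenance: placeholder}
    nonfatal_ic_mb:           {value: 60,  provenance: placeholder}
    nonfatal_extracranial_mb: {value: 30,  provenance: placeholder}
    crnmb:                    {value: 2,   provenance: placeholder}
    cteph_onset:              {value: 40,  provenance: placeholder}

utilities:
  baseline: 0.825              # EQ-5D-5L population value, ages 60-70
  baseline_provenance: placeholder
  event_decrements:            # one-cycle decrement at event occurrence
    recurrent_dvt:            {value: 0.09, provenance: placeholder}
    recurrent_pe:             {value: 0.15, provenance: placeholder}
    nonfatal_ic_mb:           {value: 0.30, provenance: placeholder}
    nonfatal_extracranial_mb: {value: 0.10, provenance: placeholder}
    crnmb:                    {value: 0.02, provenance: placeholder}
  state_decrements:            # recurring per-cycle decrement while in state
    cteph:                    {value: 0.27, provenance: placeholder}
    pts:                      {value: 0.07, provenance: placeholder}
    post_ic:                  {value: 0.10, provenance: placeholder}
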