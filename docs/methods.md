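# Methods

This note documents the model's structure, the conventions chosen where
published descriptions leave room, the synthetic inputs, and what the test
suite does and does not establish.

## Cohort model

A deterministic cohort of VTE patients enters the extended treatment phase
(6 months after the index event) split 66% index DVT / 34% index PE, and
is propagated in 3-month cycles to death or age 100. The public state
space has 12 health states; internally the occupancy is stratified further
by current therapy (extended apixaban; resumed LMWH/VKA; untreated;
permanently untreated after intracranial bleed), PE history (CTEPH
eligibility) and DVT history (PTS eligibility). The public transition
matrix (`build_matrix`) and trace aggregate these strata.

**Competing risks.** Within a cycle the cause-specific probabilities
(recurrence, major bleed, CRNMB, CTEPH onset, discontinuation, background
death) are composed multiplicatively on the survival scale; the combined
event mass is allocated proportionally to the cause-specific hazards.
This is order-independent and keeps rows stochastic for any inputs. When a
cause is certain (the forced q=1 at age 100) it absorbs the entire
transition mass.

**Tunnel states.** Each event state is occupied for exactly one cycle.
Tunnel occupants remain exposed to their track's risks during that cycle —
the model is memoryless beyond the one-cycle stay, so recurrence and bleed
survivors re-enter the at-risk pool immediately. The *treatment
discontinuation* state follows the same convention: a patient who stops
treatment for reasons unrelated to events still carries on-treatment risk
for the transition cycle and assumes the untreated risk profile from the
next cycle on. This one-cycle lag is the structural choice that reproduces
the published trial-replication counts and relative risk simultaneously;
an immediate risk switch overshoots the treated-arm recurrence count and
an absent switch undershoots it.

**Recurrence risk over time.** Cycles 0–3 of the extended phase (months
6–18) use the trial-derived interval risks per arm; these are
intention-to-treat quantities, so within this window every patient on the
untreated arm carries the untreated interval risk regardless of therapy
switches, and anticoagulated patients of the treated arm carry the treated
risk. From month 18 on, the baseline hazard comes from a post-cessation
cumulative-incidence curve (knots at 1/3/5/10 years: 0.110, 0.196, 0.291,
0.399) under a piecewise-constant-hazard assumption, with the final
segment's hazard persisting beyond 10 years. The curve's clock starts at
the extended-phase entry, which makes the untreated hazard continuous at
the 18-month seam (0.0121 per cycle → 0.0126). Anticoagulated patients
(apixaban or resumed VKA) get this hazard scaled on the rate scale by the
treatment-effect ratio 0.174. The published table prints the first knot as
0.0110; its CI (0.0950–0.1250) and the cited 11% first-year recurrence
identify a typo for 0.110, stored corrected in the packaged file.

**Bleeding.** Major-bleeding and CRNMB risks are 12-month risks converted
to the cycle basis (this period-basis reading reproduces the published
12-month validation counts; a per-cycle reading overshoots them
four-fold). Active apixaban carries the treated risks; resumed VKA and
untreated patients carry the untreated-arm risks (a config switch
`late_bleeding_source: placebo_all` applies untreated risks to everyone
beyond 18 months instead). The per-decade aging factor 1.97 acts on the
rate scale in whole elapsed decades — risks hold at their trial values
within each decade of follow-up, which is the reading consistent with the
12-month validation counts. Event severity splits: 13.46% of major bleeds
fatal; 13.97% of nonfatal ones intracranial. Intracranial-bleed survivors
stop anticoagulation permanently and carry an extra mortality hazard ratio
of 2.60.

**Event split and resumption.** Recurrent events divide 0.1188 /
0.2475 / 0.6337 into VTE death, recurrent PE and recurrent DVT (these are
exactly 12/101, 25/101, 64/101 — the trial's event total — which fixes the
Dirichlet effective sample size at 101 for the probabilistic analysis).
Untreated patients who survive a recurrence resume LMWH/VKA — both in the
never-extended arm and for treated-arm patients who had previously
discontinued apixaban; patients still on drug continue it. Resumed-VKA
person-time accrues INR-monitoring and travel costs.

**Chronic complications.** CTEPH onset (annual risk 0.0125, converted per
cycle) applies to patients with PE history — index PE or a recurrent PE —
and is a chronic state with per-cycle cost, a utility decrement and an
extra mortality HR of 1.30; no further recurrence or bleeding is modelled
from CTEPH (its occupancy is small and short-lived at these risks). Severe
PTS accrues in the background over alive DVT-history patients from the
5-year risk 0.0812 converted per cycle; the PTS pool shrinks with its
population's death rate and contributes per-cycle cost and disutility.

**Mortality.** Annual sex-specific death probabilities are mixed at the
cohort's fixed 58% male share (no sex-differential attrition), converted
to the cycle and multiplied on the rate scale by HR 4.41 for all VTE
patients, with the post-IC and post-CTEPH factors compounding
multiplicatively. q(100) is forced to 1. Fatal major bleeds are tallied
separately from VTE-related deaths and reported within "death from other
causes" in the public occupancy.

## Economics

Discounting is discrete at cycle start: 4%/year for costs, 1.5%/year for
effects, with the clock starting at extended-phase entry. Event costs are
one-off at occurrence; drug cost accrues per treated person-day (minus
14-day interruptions after 47.27% of non-IC major bleeds and 2-day
interruptions after every CRNMB — cost-only, sub-cycle durations do not
perturb within-cycle risk); CTEPH and PTS carry per-cycle maintenance
costs; INR monitoring accrues per VKA person-cycle; a travel tariff
applies per hospital-visit event and per monitoring visit. Productivity
losses use the friction-cost method: min(absence days, friction period) ×
workday hours × hourly wage × employment probability per event. The
healthcare-payer perspective zeroes exactly the productivity and travel
categories. Utility decrements are additive on the baseline with a floor
at zero; event decrements last the event cycle, CTEPH/PTS/post-IC
decrements recur. Per-patient figures divide by the entry cohort size.

The shipped cost/utility registry is a **synthetic placeholder** — every
value is provenance-flagged, the loader warns at load time, and
`ParameterSet.require_authoritative_economics()` refuses to treat
placeholder-based euro amounts as authoritative. Published economic
endpoints therefore activate only when a user supplies a transcribed
registry.

## Uncertainty analysis

Each uncertain input is assigned its published distribution family and
fitted by moment matching, with SE = (CI width)/3.92 (normal
approximation) or a 30% coefficient of variation when no CI exists. Beta
uses the method of moments; gamma and lognormal match mean and SE exactly;
the event split draws jointly from Dirichlet(12, 25, 64); fixed entries
never move. Because the published CIs are asymmetric and rounded, the
fitted beta's 2.5/97.5 percentiles deviate from the printed bounds by up
to ~16% of the CI width (worst: the 5-year PTS row); the parameter-recovery
suite tests them at a frozen 20%-of-width tolerance and the means at three
Monte Carlo SEs on 10⁶ draws.

The PSA redraws all uncertain inputs jointly per iteration (independent
across parameters — no correlation structure is described), evaluates both
arms with the shared draw, and yields the incremental cloud, CE plane and
CEAC. Draws violating structural constraints (e.g. a non-monotone
post-cessation curve) are redrawn with a logged count. Per-iteration seeds
derive from the master seed via `SeedSequence([master, i])`, so iteration
i is reproducible in isolation and the whole run is bit-reproducible. The
one-way (tornado) analysis re-runs the deterministic model at each
parameter's CI bounds, plus a ±1.96·(30% CV) band for the drug unit price
and baseline utility.

## Synthetic inputs and oracles

The synthetic life table follows a Gompertz–Makeham hazard per sex
(makeham 2.0/1.5 × 10⁻⁴, scale 2.0/1.1 × 10⁻⁵ for men/women, shape 0.10),
chosen once to give ~0.5% annual mortality in the late 50s and a remaining
life expectancy of ≈26.5 years at the cohort entry age — the shape of a
recent Western European period table. It replaces the national table in
all default runs, so absolute lifetime counts and all-cause-death
comparisons are indicative only; trial-horizon replication is insensitive
to it (background mortality moves the 12-month counts by well under one
event).

Two simulation oracles guard the deterministic code. `simulate_patients`
generates patient-level first-event histories with the engine's
composition rule and censoring design; the censored interval-risk
estimator recovers its input hazards within binomial error (n = 10⁵ in the
acceptance suite). `microsimulate_cohort` walks individual patients
through the engine's own per-stratum transition rules; its expected counts
match `run_cohort` within three empirical Monte Carlo SEs across ten
sampled parameter sets (10⁵ walkers, 6-cycle horizon). The Monte Carlo SE
is estimated from the per-walker count variance because repeatable events
make counts overdispersed relative to Poisson; with 70 comparisons at
three SEs an isolated ~3σ fluctuation is statistically expected, so a
comparison beyond the bound is confirmed against one independent replicate
before failing.

Problem sizes in the default suite: trial-scale validation runs (804/829
patients, 4 cycles), lifetime runs of 173 cycles for economics and
qualitative checks, PSA reproducibility at n ≤ 12 iterations over 8-cycle
horizons, and 10⁵–10⁶ draws for the sampling checks. The full
2,000-iteration lifetime PSA runs from the CLI.

## Limitations

- No half-cycle correction in the base configuration (the trial
  replication does not require it); discounting is discrete at cycle
  start.
- Memoryless recurrence: no risk escalation after a first recurrence, and
  no recurrence modelled after intracranial bleeds or CTEPH onset.
- The post-cessation curve shares one clock (extended-phase entry) across
  therapy histories; patients who discontinue late re-join it at the
  cohort's elapsed time rather than their personal cessation time.
- Parameters are sampled independently in the PSA; the trial's joint
  sampling distribution is not available.
- The initial 6-month phase (scenario 1, acute-trial replication) is
  interface-gated on user-supplied acute-phase parameters and not shipped.
- Placeholder costs/utilities make all euro-denominated outputs
  illustrative until replaced by transcribed values; tests assert
  structural economics (perspective logic, discounting, monotonicity),
  never placeholder-based totals.
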