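# Methods

## The model

`crcscreen` is an individual-level (microsimulation) Markov model of
colorectal cancer (CRC) and organised bowel-cancer screening, built to
evaluate tailored recruitment interventions for Arabic- and
Mandarin-speaking adults aged 50–74 in Victoria, Australia.  Each simulated
person moves through annual cycles until death or age 100, across three
interacting parts:

1. **Natural history** (adenoma–carcinoma pathway).  Seven health states:
   free of disease, low-risk adenoma, high-risk (progressive) adenoma, and
   CRC stages A–D (ACPS).  Progressive-adenoma incidence seeds the
   high-risk state; low-risk incidence seeds the low-risk state; annual
   transition probabilities move people along
   low→high (0.02), high→CRC A (0.05), A→B (0.05), B→C (0.28), C→D (0.28,
   assumed equal to B→C because the source table omits the row).
   Undiagnosed cancer presents symptomatically with stage-specific annual
   probabilities (A 0.22, B 0.35, C 0.59, D 1.0); the stage recorded at
   symptomatic presentation is drawn from the not-screened registry stage
   distribution (22/32/27/19%), which those probabilities were derived
   from.  After diagnosis the stage is frozen; years 1–5 follow the
   stage-specific survival table, after which patients are cancer
   survivors with general-population mortality and no recurrence.

2. **Screening**.  FOBT kits are mailed at ages 50, 52, …, 74.  Kits are
   returned with the scenario's participation rate, positive with the
   language-group positivity rate (6.4% for languages other than English),
   and positives see a GP and proceed to colonoscopy with the group's
   assessment rate (54.3%; 63.1% for English speakers).  Colonoscopy
   reveals the latent state: adenomas are removed (polypectomy) and the
   person enters surveillance; latent cancer is diagnosed with its stage
   drawn from the screen-detected distribution (49/19/24/8%) — the stage
   shift that is the model's central benefit mechanism.  Decliners of
   colonoscopy move permanently to natural history, where cancer can only
   present symptomatically.

3. **Surveillance**.  After adenoma removal: GP visit and colonoscopy
   every 5 years until age 75, removing any adenoma found and diagnosing
   any latent cancer.

Within a cycle the order is fixed: mortality → screening/surveillance →
symptomatic diagnosis → at most one progression step.  There is no
half-cycle correction.

### Colonoscopy outcomes: latent-state versus observed-prevalence modes

The programme's observed diagnostic-assessment outcome mix
(87.40 / 6.09 / 5.65 / 3.13%, renormalised from a printed sum of 102.27%)
can be used in two ways.  `colonoscopy_outcome(..., mode="prevalence")`
samples the outcome from that mix and imposes it on the individual.  We
found this makes marginal screening *harmful*: an imposed 3.1% cancer
probability per colonoscopy exceeds the latent cancer prevalence of
screening participants several-fold and is age-flat, so extra
participation manufactures excess, early-onset cancers — full-programme
screening then *lowers* QALYs, which contradicts both the premise that
participation changes the stage at diagnosis rather than incidence and the
15–33% screening mortality reductions reported in the literature.  The
default mode therefore reveals the latent state at colonoscopy and treats
the observed prevalence as a validation benchmark; the prevalence mode
remains available and tested.

### Initial latent prevalence

Cohorts are sampled at their 2019 ages but latent disease accumulates over
decades, so each run starts with a burn-in: natural history from age 50 to
the entry age, with anyone who would have died or been diagnosed replaced
by a disease-free person of the same age (a renewal approximation of the
alive, undiagnosed 2019 cross-section).  Pre-2019 screening history is not
replayed; the resulting prevalence is therefore somewhat high for a
partially screened population, and somewhat low through the renewal
resets.  Without the burn-in, a one-year recruitment uplift applied in
year 0 finds an entirely disease-free cohort and has exactly zero health
effect.

### Incidence calibration

The source table's progressive-adenoma incidence rows (0.0038–0.0068 per
year) are roughly twice the values implied by their own stated derivation
(CRC incidence shifted 20 years: 0.0019–0.0037).  With the printed rows
plus the burn-in, the model predicts ~73 CRC cases/year at Mandarin
population scale against the registry-consistent 46–47; with the
rule-derived rows it predicts ~45.  The package default is the derived
schedule (`incidence_preset="derived"`); the printed rows are available as
`incidence_preset="printed"`.  Low-risk incidence is always
`progressive/0.24 − progressive`; the printed low-risk rows (which
contradict that identity) are kept as `low_risk_preset="printed"`.

### Mortality accounting

The stage-year survival table is interpreted as all-cause survival for
cancer patients (it replaces background mortality in years 1–5 after
diagnosis).  A death in that window is attributed to CRC with probability
`(q_stage − q_background)/q_stage` — the excess-hazard share — so that
counted CRC deaths are cause-specific and comparable with registry death
counts.  Attribution reuses the mortality uniform, adding no extra draws.

## Economics

Healthcare perspective, 2019 Australian dollars, 50-year horizon, costs
and QALYs discounted at 5%/year (0% and 3.5% in sensitivity analyses).
Event costs: kit + postage $10.40 per mail-out, laboratory $17.85 per
returned kit, GP $37.60, colonoscopy $2,258 (no polypectomy) or $4,203
(polypectomy), and a stage-specific lump-sum treatment cost at diagnosis
(A $40,999 … D $90,272, the stage-D figure averaging bevacizumab use).
Utilities: population norms 0.80/0.76/0.70 (ages 50–69/70–79/80+), CRC
stages A–C 0.74, stage D 0.68, survivors revert to the age norm; the dead
contribute zero.  Costs accrue at the start of the event's cycle;
utilities accrue per cycle lived.  Intervention programme costs
($120,863 Arabic, $120,337 Mandarin) are spread over the eligible
populations (17,522 / 38,660), i.e. $6.90 and $3.11 per person, and accrue
at year 0 of the intervention arm.

Paired arms share the cohort, the burn-in and all per-cycle uniforms
(common random numbers with a fixed stream layout: one uniform per person,
cycle and purpose), so arm differences isolate the scenario effect — the
only way sub-percentage-point participation effects are measurable at all
at n = 10,000.

## Scenarios and effectiveness

Usual practice uses the group baselines (participation 30.7% Arabic,
40% Mandarin; colonoscopy assessment 54.3%).  Intervention arms raise
participation by the scenario uplift and colonoscopy assessment to the
English-speaking 63.1%, both for one year, then revert.  Scenario uplifts
come from the effectiveness module: area-level year-over-year
participation increases minus the control state (floored at zero), giving
+1.1 pp for the Mandarin proxy area and 0 for the Arabic proxy area, with
+0.2/+1.3 pp (Arabic) and +2.4 pp (Mandarin) as published sensitivity
levels.  The interrupted-time-series machinery (monthly kit returns with a
kits-sent offset, March–November windows) computes aggregate-rate IRRs;
negative-binomial regression confidence intervals are delegated to
statsmodels and advisory.

## Probabilistic sensitivity analysis

Every parameter with a published range is drawn uniformly over it
(transition probabilities, symptomatic-diagnosis probabilities, treatment
costs at ±10%; the FOBT kit's printed range does not bracket its value and
is treated as fixed).  Each trial re-draws parameters and a fresh
10,000-patient cohort and runs both arms with common random numbers; an
option shares the simulation seed across trials to isolate parameter
uncertainty (under which collapsed ranges reproduce the base case with a
zero-width interval).  Desk-scale runs use 200 trials (published analyses
used 2,000); 2.5th/97.5th percentiles of per-trial ICERs form the
uncertainty interval, and trials with exactly zero QALY difference are
excluded and counted.

## Synthetic inputs and what they stand for

Census age tables, stage-specific survival, the background life table and
register-style monthly kit series are generated by `synthetic_data` with
known truth, because the originals are not published:

* census profiles are smooth exponentials in age whose 2019 linear
  interpolation hits 17,522 / 38,660 exactly (15% inter-census growth);
* five-year survival targets are stage-graded at 0.95/0.85/0.65/0.15
  (constant conditional annual survival), a clinically plausible ordering,
  not the study's actual table;
* background mortality is Gompertz–Makeham,
  `q(age) = 5e-4 + 2.5e-3·exp(0.092·(age−50))`, forced to 1 at age 100;
* kit series are negative-binomial (size 60, matching the published IRR
  confidence-interval widths) around rate × kits-sent with a known true
  rate ratio.

Results that flow through these fixtures — absolute QALYs and costs per
person, ICERs, case and death counts — are approximations of the study
setting, not reproductions.

## Problem sizes

Base-case comparisons pool replicated paired runs of 10,000 individuals
over 50 years (40–60 replicates in the shipped analyses); validation uses
one 20,000-person arm; PSA uses 200 trials of 10,000; property checks use
100,000 replicates per probability and 40,000–60,000-person cohorts
against the matrix-product oracle.

## Known limitations and an honest negative result

The model validates well against the registry benchmarks (~45 CRC
cases/year and ~7–8 CRC deaths/year at Mandarin population scale, within
±25% of 46.5 and 8), and whole-programme screening is beneficial
(ΔQALY ≈ +0.003/person and −16% CRC deaths versus no screening).  The
published scenario-level results, however, are not mechanically
reproducible from the stated design: a +0.2 pp participation uplift
lasting one year changes ~10 participation decisions and ~9 colonoscopy
follow-ups per 10,000 people, which bounds the per-person QALY gain at
roughly 1e-4 even if every extra screen were worth 0.3 QALYs.  The
published incremental QALYs (0.005–0.024 per person, hence ICERs of
$749–$2,768) are one to two orders of magnitude above that bound, and of
the same order as the Monte Carlo noise of a 10,000-patient run.  In this
implementation the pooled incremental QALYs are ~1e-5 to 1e-4 per person
(statistically indistinguishable from zero for the smallest uplift: most
10,000-patient realisations contain *no* individual whose health outcome
changes), so ICER point estimates are unstable and two to three orders of
magnitude above the published values, and only a minority of PSA trials
fall below the $50,000/QALY threshold.  The corresponding end-to-end tests
assert the published quantities and fail; they are retained deliberately
as a record of the discrepancy.

Other limitations: no family-history risk, no adenoma regression, no
colonoscopy adverse events, constant 2019 incidence over the horizon, no
screening outside the organised programme, independent participation
draws across rounds (no persistent never-screener class), and decliners
of colonoscopy exit screening permanently.
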