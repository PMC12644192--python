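# Methods

## Study design implemented

The pipeline implements a retrospective new-user, active-comparator cohort
design on hospital administrative claims. Patients newly starting either
nab-paclitaxel alone (control) or atezolizumab 840 mg plus nab-paclitaxel
(exposure) for breast cancer enter follow-up at their first study-drug
dose (the index date) and are observed until the earliest of six censoring
events. The estimand is the incidence rate ratio (exposure/control) of
severe infections in the treated population (ATT), obtained by
standardized mortality/morbidity ratio weighting: treated patients keep
weight 1, controls are reweighted by the propensity odds PS/(1−PS).

### Index date and treatment groups

The index date is the earlier of the first nab-paclitaxel dose and the
first 840 mg atezolizumab dose. A patient is *exposure* when both drugs
appear within `combination_window_days` (default 28, one treatment cycle)
of the index; *control* when only the taxane does. The window is needed
because claims record administrations, not regimens: a combination partner
started later than one cycle after the taxane is treated as a regimen
switch (censoring rule 5), not as combination therapy. Patients whose only
qualifying drug is 840 mg atezolizumab (no taxane within the window)
receive neither study regimen and are not candidates, and the 1200 mg dose
alone — approved for other tumour types — never defines candidacy.
Candidates additionally need a confirmed breast-cancer diagnosis in the
index month (month-granular diagnoses make this the only checkable
reading of "initiated in the month of diagnosis") and an index inside the
eligibility window (default 2019-11-27 to 2022-05-31).

### Exclusion criteria

Applied sequentially, in the reported order, each counting removals among
the survivors of the previous steps: (a) ≤89 days of data before the index
without a pathological-diagnosis procedure; (b) any study-drug
administration strictly before the index, at any dose — with the index
defined as the first 840 mg/taxane dose, a prior 1200 mg administration is
the only way this criterion can fire; (c) a severe infection
(original definition) with onset in [index−30 d, index−1 d]; (d) any
HER2-positive code in a month up to and including the index month; (e)/(f)
history of adjuvant/neoadjuvant chemotherapy or of other cancer regimens
(separate configurable drug-code lists — deliberately distinct from the
broad anticancer-history covariate, which has high prevalence and must not
exclude anyone); (g) index date equal to the last recorded visit. "History
of" criteria scan the entire available lookback. An
`order_independent_counts` switch reports per-criterion counts evaluated
on all candidates regardless of order.

## Outcome definitions

Severe infections are phenotyped from claims, not adjudicated. All
definitions require a *confirmed* (non-suspected) infection diagnosis.

| name | hospitalization | primary reason | immunological test | IV antibacterial | COVID codes removed |
|------|-----------------|----------------|--------------------|------------------|---------------------|
| original | yes | yes | yes | – | – |
| def1 | yes | yes | – | yes | – |
| def2 | – | – | – | yes | – |
| def3 | yes | yes | yes | – | yes |

* **Original**: one event per hospitalization whose primary reason is a
  confirmed infection diagnosis, with an immunological infection test in
  the window [first day of the calendar month before the admission month,
  discharge date]; onset = admission date. Calendar-month semantics are
  the natural reading of "month before admission" for month-granular
  records.
* **def1**: as original but the test criterion is replaced by an IV
  antibacterial course starting during the hospitalization. The course
  must also satisfy def2's diagnosis–course linkage, which makes the
  nesting def1 ⊆ def2 exact by construction rather than merely typical.
* **def2**: one event per (confirmed infection diagnosis, IV antibacterial
  course) pair whose diagnosis month overlaps
  [course start − `def2_lookback_days` (default 7), course end];
  onset = course start (there is no admission date to anchor on).
* **def3**: original after deleting COVID-coded diagnosis records —
  records, not hospitalizations, so an admission can still qualify through
  a different confirmed infection diagnosis.

Antibacterial **courses** are maximal runs of daily IV antibacterial
records merging gaps of at most `gap_days` (default 1) missing days;
duration is the calendar span end − start + 1; the treatment setting at
course start is inpatient if any record on the start date is inpatient.
Only the earliest event per patient inside the observation window feeds
the analysis; the detector can return all events for diagnostics.

## Follow-up and person-time

Observation ends at the earliest of (1) index + 210 days, (2) outcome
onset, (3) regimen end, (4) a 1200 mg dose of the combination partner,
(5) a control patient's first 840 mg dose after the combination window,
(6) any other anticancer drug. Rules 4–6 censor at the *day before* the
trigger prescription. The minimum is taken over trigger record dates with
the one-day subtraction applied only when such a rule wins, so an outcome
on the same day as a censoring prescription still counts as an event;
remaining ties resolve in the priority order outcome > horizon > 1200 mg >
switch > other-anticancer > regimen end. "Regimen end" is operationalized
as the last study-drug administration plus `grace_days` (default 28, one
cycle), because claims carry no discontinuation record. Rule 5 is
observable only for controls: an exposure patient who drops the
combination partner is indistinguishable in claims from one continuing.
Patients whose earliest trigger precedes the index keep zero person-time
and are flagged, not dropped. Person-years are Σ w·days/365.25.

## Covariates and weighting

Thirteen covariates are derived from pre-index records: age at index
(index year − birth year, the only arithmetic a birth year supports);
breast-cancer duration in months from the earliest confirmed breast-cancer
diagnosis month; COVID-season indicator (index ≥ `covid_season_start`,
default 2020-04-01, the first national state of emergency); four
diagnosis-history flags (renal/hepatic impairment, nodal metastasis,
diabetes) counting confirmed diagnoses in months strictly before the index
month; a comorbidity score summing configurable weights over *distinct*
comorbidity categories (17 categories with standard weights ship as
placeholders; no age points, age being its own covariate); three
procedure-history flags and anticancer-drug history strictly before the
index date; and steroid use within `steroid_window_days` (default 90) —
a current-use covariate, not lifetime history.

The propensity model is a main-effects maximum-likelihood logistic
regression (Newton–Raphson, tolerance 1e-8, ≤100 iterations), continuous
terms linear. Constant covariates are dropped with a warning. A binary
covariate with one empty treatment-by-level cell (quasi-separation — its
coefficient alone diverges) is dropped with a warning so small cohorts
remain analysable; a covariate that predicts treatment perfectly is fatal
with a diagnostic naming it. No weight truncation is applied; the maximum
control weight is logged. Overlap trimming retains each group's patients
whose PS lies inside the other group's observed PS range (boundaries
inclusive); the trimmed sensitivity analysis reuses the full-cohort PS fit
and weights on the trimmed subset without refitting.

Balance is reported as standardized differences, continuous
d = (m₁−m₂)/√((s₁²+s₂²)/2) and binary d = (p₁−p₂)/√((p₁q₁+p₂q₂)/2), with
weighted summaries under the frequency-weight convention (variance
denominator Σw−1) and weighted Ns reported to one decimal.

## Estimation

* Incidence rates: IR = E/T per person-year with natural-scale Wald CIs
  IR ± z·√(Σw²e)/T — these can cross zero, which is how sparse
  person-time incidence is conventionally printed in this design; zero
  events give the degenerate [0, 0] interval, flagged.
* Rate ratios: IRR from the weighted rates; log-scale Wald CI
  exp(ln IRR ± z·√(1/E*ₑ + 1/E*𝒸)) with effective counts
  E* = (Σwe)²/(Σw²e) (equal to raw counts when unweighted). A continuity
  constant (0.5) enters both counts only when one is zero; two zero counts
  are undefined and flagged. z is fixed at 1.96 for α = 0.05. This
  fixed-weight variance ignores the estimation of the propensity score and
  is therefore mildly conservative: in the null-scenario experiment the
  claimed SE exceeds the empirical replicate SD by ≈10–15%, giving
  empirical coverage near 97% rather than 95%.
* Sample-size planner: T per group = n·weeks·7/365.25 person-years,
  expected control events = rate·T, exposure events = ratio·rate·T, CI by
  the same log-scale formula at the expected counts. With 250 patients per
  group, a control rate of 16.1 per 100 person-years, 16.1 weeks of
  observation and an assumed twofold ratio this returns the classical
  (1.01, 3.95) interval; the result is invariant at 2-dp to the
  weeks→years divisor (52 vs 52.1775).
* Kaplan–Meier: weighted product-limit estimator with weighted event and
  at-risk sums; censoring after events at tied times.

## The synthetic generator

`SimulationParameters` defaults define the reference scenario:

* n = 5000 patients; covariate marginals calibrated to the published
  cohort's baseline table (age 59.2 ± 12.65; breast-cancer duration
  24.9 ± 26.7 months truncated at the available lookback; binary
  prevalences at the pooled two-group values, e.g. steroid use 48.1%,
  nodal metastasis 39.5%; comorbidity score ≈ N(6.65, 3.3) rounded and
  clipped to [0, 16] then decomposed exactly into weighted categories);
  covariates drawn independently.
* Treatment by a logistic model whose coefficients are the 2×2 log odds
  ratios implied by the published between-group imbalances (nodal
  metastasis +1.08, radiotherapy history +1.41, steroid use −0.64, …),
  intercept solved numerically so the expected treated fraction hits its
  target (default 0.5).
* One exponential severe-infection time per patient with hazard
  0.35/py × exp(β·(x−x̄)) × RR^treated; default RR = 2; hazard
  coefficients on steroid use (0.5), nodal metastasis (0.5), radiotherapy
  (0.6), diabetes (0.3), comorbidity score (0.05/point) and age
  (0.01/year). The 0.35/py baseline matches the broad (diagnosis +
  antibacterial) definition's scale rather than the stricter
  hospitalization-anchored one. Only the first event matters (observation
  ends at onset), so recurrent events are not simulated.
* Weekly taxane administrations for a truncated-geometric number of weeks
  (mean 16, max 30) with the partner q2w in the exposure arm; deliberate
  subpopulations trigger each exclusion and censoring rule; index dates
  split around the COVID-season start (86% after).
* Phenotype emission defaults to 1.0 with zero background noise — the
  perfect-phenotype reference under which detected events equal true
  events. `SimulationParameters.noisy()` degrades emission
  (hospitalization 0.7, primary flag 0.7, test 0.8, antibacterial 0.85)
  and adds background hospitalizations, tests, antibacterial courses and
  unrelated diagnoses, emulating the sensitivity loss real claims
  phenotyping suffers.
* Every table draws from its own child stream of the master seed, so
  adding noise never perturbs covariate draws, and identical parameters
  give byte-identical output files.

`expected_summaries` is the analytic oracle: it samples only the covariate
mixture (fixed internal seed) and uses the exponential identities
E[events] = 1−e^{−λC}, E[time] = E[events]/λ per patient to compute exact
expected group rates and rate ratios, with the SMRW control expectation
reweighted by the true propensity odds.

### What passing the synthetic tests does and does not show

The generator draws covariates independently, uses a correctly specified
(linear-logit) treatment model, emits covariate records that the derivation
recovers without error, and has no unmeasured confounding, interference,
or informative censoring beyond the implemented rules. Recovery of the
true rate ratio under these conditions validates the *pipeline mechanics*
— phenotyping, censoring arithmetic, weighting algebra — not the causal
adequacy of SMRW on real data, where none of those assumptions is
guaranteed. One designed subtlety survives even here: with heterogeneous
hazards and a finite horizon, the ratio of person-time rates is not
exactly the hazard ratio (higher-hazard patients contribute relatively
less exposure time, more so under treatment), so the SMRW estimate centres
on ≈1.94 rather than 2.00 under the default scenario — the analytic oracle
reproduces this value, and the replicate experiments test against it
within ±0.1 of the design value.

## Numerical and reporting choices

Dates are closed-interval; "day before" subtracts exactly one calendar
day; a diagnosis month overlaps a day interval iff the month's first-to-
last-day span intersects it. Diagnosis code lists match by prefix
(hierarchical codes), drug and procedure lists exactly, declared per list
in the configuration. Rates and IRRs are rounded to 2 decimals in
formatted tables, standardized differences to 3, weighted Ns to 1; all
computations keep full precision internally. Shipped code lists are
synthetic placeholders — structurally faithful, with invented code values
— and every list is replaceable through `load_code_lists`.

## Known limitations

* The claims schema is a minimal sufficient reconstruction, not a faithful
  copy of any proprietary extract format.
* Death is not modelled (claims carry no death date here), so there is no
  competing-risk handling; regimen end is inferred, not recorded.
* The weighted-CI variance treats weights as fixed; coverage is slightly
  conservative (see above). A full M-estimation sandwich accounting for
  propensity estimation is out of scope.
* The 210-day horizon is taken as given from the design it implements; the
  feasibility evidence behind it is not re-derivable.
* Exclusion (b) can only fire through a prior 1200 mg administration given
  how the index is defined; the alternative reading (prior exposure to a
  completed regimen) is not identifiable in this schema.
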