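# Methods

## Disease-activity model

Activity is not observed; it is inferred from treatment changes. The event
detector walks each patient's date-ordered prescription stream carrying
per-molecule course state, per-class recency, and the current biologic
molecule, and emits at most one event per prescription row with priority
biologic_change > new_biologic > dose_escalation > class_addition >
new_non_biologic:

- **Course initiation.** A prescription starts a course when the molecule is
  first-ever for the patient or its last dispensing is at least
  `new_course_gap_days` (default 90) earlier. Course-initiating non-biologic
  rows are events (this makes a second steroid course in a year a second
  event, consistent with treatment-escalation guidance); within-course
  repeats at the same or lower dose are not.
- **Dose escalation** compares consecutive dispensings of the same molecule
  in the same unit; a strictly higher dose within a course is an event,
  de-escalation never is. Mixed units for one molecule raise an error
  rather than guess a conversion.
- **Class addition.** A course-initiating row of one class while a
  *different* class is ongoing (any dispensing within `ongoing_window_days`,
  default 60) is labelled class_addition rather than new_non_biologic. Both
  are single events; only the concurrency context differs. A corollary worth
  knowing: splicing a same-molecule biosimilar dispensing into an ongoing
  biologic course never adds or removes an event, but it keeps its class
  "ongoing" and can therefore relabel a later initiation of another class
  from new_non_biologic to class_addition.
- **Biologics.** The first-ever biologic, and a re-initiation of the same
  molecule after a course gap, are new_biologic; a different molecule from
  the current biologic is biologic_change. Originator↔biosimilar switches of
  the same molecule are deliberately silent.

Same-day duplicate rows of one product are deduplicated; same-day rows of
different products are evaluated independently in (date, drug_name) order.

Assessment periods are `n_periods` (default 4) contiguous half-open
12-month windows anchored at the study start (2016-03-31). Anchoring to
fixed study years — rather than each diagnosis date — makes every cohort
member contribute exactly `n_periods` observations, matching the exact 4×
observation-to-patient ratios of the source setting's characteristics
table. The price is that pre-diagnosis periods exist, contain no events,
and classify as remission, biasing remission percentages upward and
baseline (first-period) active fractions downward; `ActivityParams.anchor`
is configurable for sensitivity analyses. A period is active when its event
count strictly exceeds `active_event_cutoff` (default 2).

Biologic timing: *early* means the first biologic falls 0–91 days
(inclusive; "3 months" is read as 91 days for determinism) after **any**
index event. Under the default strict second-event rule, a start preceded
by two or more events within its own assessment period is late even inside
that window; `BiologicTimingRules(strict_second_event=False)` disables the
clause, which is the single most uncertain rule in the codebase — the two
lateness clauses of the underlying definition cannot be disentangled from
text alone. Note the strict rule is demanding: with ~5 events per active
year, a start even a few weeks after the index event is often already past
a second event, so early shares sit well below naive expectation.

## Cohort rules

Candidates need at least one IBD diagnosis code; UC-only codes → UC,
CD-only → CD, both → IBD_undefined (code order and gap ignored). Inclusion
requires the earliest code date inside the half-open window
[2016-03-31, 2020-03-31). Exclusions are applied in fixed order — under-age
(age at diagnosis < 18; the published age range starts at 18, so ≥ 18 is
included), non-incident, biologic exposure before diagnosis (lookback
configurable, default all history), resection before the first biologic (or
before diagnosis when never treated) — giving each dropped patient one
reason. Every input patient lands in exactly one of cohort or exclusion
log.

## Costs

Encounters are labelled with their period's status; per-patient totals are
formed first (zero-encounter patients contribute zeros; a switch restricts
visit-count means to visiting patients, cost means always keep the zeros)
and mean/SD (sample SD, n−1; 0 for a single patient) are taken across
patients within each grouping cell. Cells with nothing observed are
omitted. Biologic drug costs come from a per-prescription tariff table
(drug-name lookup with molecule fallback) — a configurable stand-in for
commissioner pricing, since practice-level prescribing-cost inputs are not
available; the bundled values are order-of-magnitude list prices, not
estimates. Inpatient stays are assigned to the period of the admission
date. Because status-split totals accumulate over however many periods a
patient spends in each status, and remission periods usually outnumber
active ones under this anchoring, remission totals for cheap high-volume
settings (primary care, community) can exceed active totals even when
per-period intensity is higher in active disease.

## Statistics

The two-group comparison is the two-sample Wilcoxon rank-sum (the groups
are independent patient sets, so the signed-rank variant does not apply).
For pooled n ≤ 14 the p value is exact: all C(n, n_a) assignments of the
observed pooled values are enumerated (conditioning on the data, so ties
need no correction) and the two-sided p is twice the smaller tail, capped
at 1. Larger samples use the normal approximation with continuity and tie
corrections (scipy). Raw p values are reported against α = 0.05 with no
multiplicity correction, mirroring the exploratory reporting style this
pipeline reproduces; the caveat stands. Displayed p values floor at
`<0.0001`. Percentages round half-up using exact integer arithmetic.
Groups with fewer than two patients yield p = None with an
`insufficient` flag. Counts 1–4 in rendered tables are suppressed to
`<5`; a suppressed count also hides its percentage, which would otherwise
reveal it.

## Synthetic-data generator

Each patient's course is a first-order two-state chain over the period
grid: pre-diagnosis periods are remission; the diagnosis period is active
with probability `p_active_initial` (0.35); thereafter states persist with
`p_stay_active` = 0.5 and `p_stay_remission` = 0.9, chosen to put the
long-run remission share of observations near the low-80s percent regime.
Diagnosis dates are uniform over the window; configured fractions carry
exclusion features (prevalent diagnosis before the window 5%, under-age 2%,
prior resection 3%). The diagnosis mix is 76/18/6% UC/CD/both-coded.

Event-generating prescriptions are Poisson per period —
`event_rate_active` = 5, `event_rate_remission` = 0.5 — on distinct days,
cycling through a per-patient shuffled pool of ten conventional molecules.
Each such prescription is constructed to fire exactly one detector event:
a new course at the molecule's base dose when the previous use is ≥ 90 days
back, otherwise a ×1.5 dose escalation. Up to two maintenance repeats at
unchanged dose follow within 28-day intervals (never crossing the
molecule's next event), firing nothing. About 5% of patients
(`p_biologic`) start a biologic — anti-TNF (infliximab/adalimumab) or, with
probability 0.3, non-anti-TNF (vedolizumab/ustekinumab) — anchored near the
first active period's first event, with 8-weekly repeats and an optional
mid-course same-molecule biosimilar switch (25%) as a deliberate
non-event distractor. The initiation adds one new_biologic event, a
negligible (< 0.1 event/period) calibration offset.

Encounters are Poisson per period per care type at status-dependent rates
(per 12 months: primary care 8/7 active/remission, outpatient 2.2/1.0,
elective inpatient 0.8/0.55, non-elective 0.55/0.4, community 1.0/0.7 —
stand-ins; the source setting publishes no visit-rate distributions). Costs
are log-normal per care type (arithmetic means £2,500 elective, £3,000
non-elective, £150 outpatient, £39 primary care, £120 community; σ
0.3–0.8), right-skewed as real cost data are. Inpatient length of stay is
1 + Poisson(mean − 1) days with means 4 (active) and 3 (remission).

Under these conditions, classification recovers the latent status for ≈ 97%
of patient-periods at n = 500: the residual error is mostly Poisson — an
active period emits ≤ 2 events with probability
P(Pois(5) ≤ 2) ≈ 0.12, a remission period > 2 with
P(Pois(0.5) > 2) ≈ 0.014.

What the generator does **not** emulate: real coding vocabularies (a
configurable drug-name lookup replaces them), comorbidity and frailty,
demographic structure (ages uniform 18–90), care-seeking behaviour beyond
Poisson counts, seasonal or secular trends, and informative missingness.
Passing tests therefore demonstrate that the *rules* are implemented
correctly and recover a known generating process — not that the rules
measure clinical activity well in real records.

## Numerical and design notes

- All period and window intervals are half-open; boundary dates belong to
  the later period.
- Determinism: a single `numpy` Generator seeded from `SimulationConfig.seed`
  drives generation in fixed patient order; identical seeds give identical
  tables.
- Problem sizes used by the test and acceptance runs (500 patients for
  recovery and identity checks, 1,000 for calibration and cost
  conservation, 100 permutation replicates, 200 oracle sample pairs) are
  large enough to make the stochastic checks stable across seeds while
  keeping a full run near-instant.
- Duration-of-remission estimation is deliberately out of scope: with
  yearly assessment it is not computable. Indirect/societal costs and
  visit-reason text are likewise out of scope.
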