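# Methods

This note documents the models, rules, and numerical conventions behind
`oncolot`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate about real claims data.

## Data model and calendar conventions

Claims are four tables: patients (sex, birth year, death date if captured,
last hospital visit), monthly diagnoses (ICD-10, suspected flag), dated
prescriptions (drug code, inpatient/outpatient setting, remuneration
points), and dated procedures. Diagnoses carry a year-month only, matching
the monthly granularity of Japanese claims; all diagnosis-level predicates
are therefore evaluated on calendar months. Day intervals are calendar-day
differences and windows are closed. One month = 30.4375 days (365.25/12),
the usual survival-analysis convention, exposed as
`oncolot.schema.DAYS_PER_MONTH`; day counts are converted to months by
division. Suspected-flag diagnoses are ignored by every cohort and AE
predicate (standard practice for Japanese claims), configurable.

## Cohort rules

* Perioperative detection anchors on breast-surgery procedure dates: a
  regimen whose first prescription falls within `adjuvant_window_days`
  (default 92) after a surgery is adjuvant; one whose last prescription
  falls within 92 days before a surgery is neoadjuvant. An
  anthracycline-containing episode followed by a taxane-containing episode
  with a start-to-start or end-to-start gap of ≤ 42 days forms a series
  that inherits a perioperative label when either member qualifies. The
  "3 months" windows are realized as 92 days for surgery proximity and as
  3 calendar months for the look-back (which must align with monthly
  diagnoses); both are configurable because days-versus-months is not
  canonically fixed.
* The first-line index is the start of the earliest non-perioperative,
  non-hormonal breast-cancer regimen inside the enrollment window
  (defaults 2017-01-01 .. 2022-03-31; study end 2022-09-30). A patient
  whose earliest such regimen precedes the window is not enrolled later —
  a later regimen would not be first-line.
* The minimum follow-up of 180 days is implemented as a design guarantee —
  index ≤ study end − 180 days — not as a post-hoc exclusion of
  short-follow-up patients. This matches the arithmetic of an enrollment
  window that closes six months before the data end.
* Receptor tests must be strictly before the index date; the
  hormonal/anti-HER2 exclusion scans the whole data period.
* The Charlson comorbidity index uses a Quan-style ICD-10 prefix map with
  the original category weights, shipped as an editable CSV
  (`data/charlson_map.csv`, prefixes flattened to the dotless 3–4
  character form the schema enforces). Hierarchy: metastatic cancer
  supersedes any malignancy, moderate/severe liver disease supersedes
  mild, complicated diabetes supersedes uncomplicated. Baseline flags and
  the index use diagnoses up to and including the index month.
* Prior non-breast primary cancer is a reported characteristic, not an
  exclusion.

## Lines of therapy

Components of a regimen are the breast-cancer drugs whose first
prescription on/after the anchor falls within `combo_window_days`
(default 28); the set is matched against a named regimen catalog
(`data/regimen_catalog.csv`), longest match first, with an ad-hoc
slash-joined name as fallback. Classification: any anthracycline ⇒
anthracycline-containing; otherwise any taxane **or any immune checkpoint
inhibitor** ⇒ taxane-containing; otherwise other. (ICI regimens are too
rare to form their own category and are conventionally grouped with the
taxane-based ones, including ICI combinations without a taxane.)

Exposure ends at the earliest of five candidates — study end, death, grace
lapse, first outside-drug prescription, last hospital visit — with ties
broken death > new drug > grace lapse > last visit > study end. The grace
period is 90 days. A gap between consecutive prescriptions exceeding the
grace period truncates the regimen at previous prescription + grace; the
same rule is applied to the tail after the final prescription (the tail is
an unbounded gap), which is the consistent reading of a truncation rule
defined only for inter-prescription gaps. A prescription of a drug already
in the regimen never advances the line. Lines beyond the third are
detected — so the third line is censored correctly at a fourth-line start —
and counted but not analyzed.

A deliberate consequence of the combination window: a drug switch cannot
be expressed within 28 days of a line's anchor, because any new drug there
is definitionally a combination component. The synthetic generator
respects this identifiability floor (below).

## Endpoints

TTNTD runs from the line index to the next treatment or death, whichever
is first; grace-lapse discontinuations and administrative ends are
censorings at the exposure end date. TTD counts discontinuation for any
cause (grace lapse), next-line start, and death as events; administratively
ended lines are censored at the last confirmed activity, by default the
final regimen prescription (`censor_activity="last_rx"`; the
`last_rx_or_visit` option uses the later of prescription and visit capped
at the exposure end — the definition of "last confirmed activity" is not
canonical, so both readings are available). Both endpoints use the
inclusive-day convention time = (end date − index date) + 1, applied to
censored times as well.

Kaplan–Meier estimation is backed by lifelines: product-limit survival,
Greenwood variance, pointwise 95% bands on the log(−log) scale (the
dominant convention in survival software, chosen because no specific CI
method is canonical for this analysis), censoring processed after tied
events. Quantiles (25/50/75%) are the first times the curve reaches
1 − q, with confidence bounds by inverting the band
(Brookmeyer–Crowley); a quantile the curve never reaches is reported as
absent. An independent hand-rolled product-limit oracle in the test suite
cross-checks the implementation.

## Adverse events

Seven categories (nausea/vomiting, neutropenia/leukopenia, febrile
neutropenia, anemia, diarrhea, ILD, peripheral neuropathy) are identified
by ICD-10 prefixes plus required AE-treatment drug classes
(`data/ae_code_map.csv`, an editable stand-in for the unpublished code
list; febrile neutropenia requires both a G-CSF and an antibiotic start).
"Same month as the start of the corresponding treatment" is parsed as: the
AE drug's first prescription within the line's follow-up shares the
calendar month of the qualifying diagnosis. The follow-up is evaluated at
month granularity (index month .. exposure-end month). When a line switch
happens mid-month, the boundary month belongs to both lines' follow-up; a
qualifying event there is attributed to the newer line only, so one
clinical event is never double-counted across lines. Frequencies use
pooled patient-line denominators: the same patient on the same regimen in
two lines contributes two to that regimen's N. AEs after regimen
discontinuation are out of scope by construction.

## Costs

Points × `yen_per_point` (default 10, the Japanese fee schedule) ÷ 1000 →
thousand yen. Claims on the exposure-end date are included (closed
interval, consistent with the inclusive follow-up day count). All claims
in the window count toward the total — including non-breast-cancer ones —
since the total is a total medical cost. Drug cost sums prescription
claims; hospitalization/outpatient split all claims by setting, so
hospitalization + outpatient = total exactly. Per-day values divide by the
follow-up day count; the cumulative scope sums a patient's available lines
with the summed follow-up as divisor, so cumulative per-day is not the sum
of per-line per-day values.

## Synthetic generator

The generator emulates the population and claim structure the analysis
assumes, with ground truth per line. Defaults are the study conditions:
per-line TTNTD medians 8.0 / 6.5 / 5.2 months, line-transition
probabilities 0.47 and 0.45, per-line regimen weights from the
treatment-pattern table, per-regimen AE probabilities from the pooled AE
table, prescriptions every 21 days (an assumption — no cadence is
canonical — flagged configurable).

Design of the trajectory process, chosen for closed-form testability:

* Every line draws an exponential TTNTD clock (rate ln 2 / median). With
  probability p the event is the next treatment (the next line's first
  prescription lands exactly there); otherwise it is death
  (`death_vs_next_treatment_ratio` defaults to 1.0 so the marginal stays
  exactly exponential; smaller values convert part of the remainder into
  lapse-then-censor trajectories, a cure-like fraction).
* Transitions are floored at combination-window + 1 days: a switch inside
  the window is definitionally a combination, so the data model cannot
  express it. The floor moves ~8% of transition times to day 29 and leaves
  the survival curve unchanged at every later time, so KM medians are
  unaffected.
* Early discontinuation is drawn independently of the event clock (prob.
  0.30, exponential stop time with median 2.5 months, lapse at last
  prescription + 90 days), keeping grace-lapse censoring of TTNTD
  non-informative — a requirement for unbiased KM recovery. A consequence
  is that synthetic TTD medians land near 4.5–6 months; reproducing the
  much shorter real-world TTD medians would require discontinuation so
  aggressive that almost no one remains at risk at the TTNTD medians,
  making the two endpoint scales impossible to emulate simultaneously
  under independent censoring. TTNTD fidelity was chosen.
* Index dates are uniform over 2017-01-15 .. 2018-06-30 (inside the
  enrollment window), so administrative truncation at the 2022-09-30 study
  end removes < 1% of first-line events and ~2.6% of cumulative
  second-line events; expected observed entry fractions are ≈ 0.467 and
  ≈ 0.206 against configured products 0.47 and 0.2115.
* The next line's regimen is resampled when its components are a subset of
  the current line's (no "new drug" could mark the switch). This slightly
  reshapes later-line regimen shares relative to the raw weights (e.g.,
  third-line shares of regimens common in the second line are deflated).
* Every patient is built cohort-compliant: receptor tests ~95–140 days
  before index (also securing the 3-calendar-month look-back), C50 in the
  index month, and — with probability 0.45 — a surgery plus adjuvant
  anthracycline episode (optionally a sequential taxane series) 400–800
  days before index. `inject_violations` produces targeted negatives for
  each exclusion filter.
* Costs are log-normal points: per-prescription drug points (medians
  6000/10000/13000 by line), monthly outpatient visit claims, and an
  inpatient episode with probability 0.35 (keeping the hospitalization
  median at zero). The generator reproduces the escalating per-day cost
  ordering across lines and the rough scale, not exact cost quantiles —
  matching all four cost-type distributions simultaneously is beyond what
  a two-parameter log-normal per claim type should be asked to do.
* Deaths beyond the data end are unrecorded (the patient is simply alive
  at the study end); `death_capture_prob < 1` additionally simulates
  out-of-hospital deaths as last-visit censorings.

What passing tests show: the pipeline's rules are internally consistent,
recover known generator parameters (KM medians within 5% at n = 20 000,
entry fractions within binomial 99% intervals), and respond correctly to
injected rule violations. What they do not show: robustness to coding
practices the generator does not emulate — dose-level claims, regimen
holidays shorter than the grace period, miscoded settings, biomarker
misclassification of the TNBC proxy, or hospital-switching loss to
follow-up.

## Problem sizes and numerics

Recovery tests and the acceptance script use 20 000 patients: the
Monte-Carlo standard deviation of a KM median of an exponential sample is
≈ 1.44·median/√n, so the third-line cohort (~20% of patients) needs that
scale for a 5% check to be a ≥ 2σ test. The full pipeline on 20 000
patients runs in ~1–2 minutes on one CPU. Percentages print half-up (two
decimals in share tables, one decimal elsewhere), mirroring how such
tables are conventionally published. Degenerate inputs: an all-censored
KM curve has no quantiles (reported absent); an empty cohort is an error
for baseline summarization; zero-claim windows cost zero.
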