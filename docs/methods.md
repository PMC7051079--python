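# Methods

## The problem the package models

National claims systems such as Brazil's DATASUS record outpatient drug
dispensings and inpatient stays in separate files without a shared
patient identifier.  Studying drug effectiveness there requires, in
order: probabilistic record linkage, reconstruction of treatment lines
from dispensing sequences, eligibility screening, confounding
adjustment, and rate estimation.  The package implements that chain and
pairs it with a synthetic-claims generator whose ground truth makes each
link of the chain measurable.

## Synthetic claims generator

The generator is the package's definition of the study conditions, not a
test fixture.  Per patient it draws:

- demographics: sex (73.2% female), age at first MS claim
  ~ Normal(34.7, 10.5) truncated to 18–76 years, region with
  probabilities (Southeast 0.60, South 0.14, Northeast 0.13, Centre-West
  0.10, North 0.03), an 8-digit ZIP;
- a first MS (ICD-10 G35) claim date, a treatment start inside the
  2013-01-01..2017-12-31 window (configurable), and a first-line
  platform drug (interferon β-1a IM/SC, β-1b SC, glatiramer);
- therapy lines: 78% switch to a second line; 55% of switches go to
  natalizumab or fingolimod, the choice following a logistic model in
  age, region, first-line drug and time in first line (so treatment
  choice is confounded); remaining switches re-use platform drugs or
  dimethyl fumarate; third/fourth lines each follow with probability
  0.25.  Line durations are lognormal in 30-day refill units (medians
  ≈ 19, 15, 10 refills for lines 1, 2, 3+), truncated at the window end;
- hospitalizations: per line, a Poisson count with rate
  `0.12 × drug ratio × m`, where the drug ratios are 1 (first line),
  0.30 (natalizumab), 0.65 (fingolimod), 0.85 (other post-platform), and
  `m = exp(γ·x_centred)` is a per-patient confounder multiplier
  normalized to population mean 1.  Normalizing `m` and giving
  time-in-first-line a zero outcome coefficient by default keeps the
  marginal first-line AHR at its configured 0.12 events/person-year;
  the same covariates drive both `m` and treatment choice, which is what
  makes the naive between-drug contrast biased.  Each stay lasts
  2 + Poisson(2) days and carries a SIGTAP-like procedure code with a
  billing quantity;
- file emission: a diagnostic work-up claim at the first MS claim date,
  monthly refills per line (interior refills dropped with probability
  0.10), one inpatient row per hospitalization, monthly same-day
  natalizumab infusion stays and a 0–1-day fingolimod first-dose
  monitoring stay — the treatment-requirement stays the >1-day rule
  must exclude.  Quasi-identifier fields are corrupted independently per
  row at rate 0.01 (dob ±1 day; one ZIP digit substituted, or blanked in
  20% of hits; sex flipped).  Pseudo-ID spaces of the two files are
  disjoint; rows are shuffled.  Small strata exercise the eligibility
  screen: 2% diagnostic-only, 4% under 18, 5% pre-window starters, 3%
  non-platform first line.

Rate magnitudes, cohort mixes and line-duration medians were chosen once
to sit in the regime of published Brazilian MS claims analyses (first-
line AHR ≈ 0.12, second-line natalizumab ≈ 0.036, drug mixes of roughly
a quarter per platform drug).  What the generator does **not** emulate:
duplicate dispensings, transcription errors in drug codes, migration
between regions, death/disenrollment, dose titration, or clinical
severity (EDSS) — so passing tests show correctness of the pipeline
mechanics and estimators under a clean data-generating process, not
robustness to every real-data pathology.

## Record linkage

Rows are collapsed per file pseudo-ID with majority-vote consensus keys
(corrupted fields are outvoted when a patient has several rows).
Candidate pairs are the union of two blocks — exact (ICD-10, 4-digit ZIP
prefix) and exact dob — scored by the Fellegi–Sunter sum of
log2(m/u) on agreement and log2((1−m)/(1−u)) on disagreement over dob,
ZIP, ICD-10, sex and region; a missing field contributes 0.  Defaults:
m = 0.95 per field; u estimated from empirical value frequencies
(probability two random cross-file records agree); threshold 0 (accept
when posterior odds favour a match, i.e. score > 0); greedy descending-
score assignment under a one-to-one constraint with stable tie-breaks
(a one-to-many mode exists; one-to-one is the default since each file
carries one pseudo-ID per patient).  Cleaning drops rows with more than
half of the key fields missing and splits patients whose member rows
disagree on dob by more than a year.

## Lines of therapy

A dispensing claim covers 30 days; same-drug claims chain into an
episode while the inter-claim gap is at most coverage + grace
(30 + 60 days, both configurable — chosen for monthly SUS dispensing);
episode end = last claim + coverage.  Overlapping episodes of different
drugs truncate the earlier episode at the later start (MS DMTs are not
co-administered; the switch date is the first claim of the new drug).
Every drug change between consecutive episodes increments the line
number — returning to an earlier drug starts a new line — while
consecutive same-drug episodes merge into one line.  Durations are
reported in months of 30.4375 days.

## Cohorts

Cohort 1 applies, in fixed order: ≥1 MS drug claim; age ≥ 18 at first
MS claim; first treatment inside the study window (patients already on
therapy before the window are excluded); platform first-line drug;
≥ 12 months from first treatment to the last observed claim in either
file (the package's reading of "follow-up in the database"); ≥ 2 lines.
The first failed criterion is the recorded exclusion reason, making the
attrition funnel reproducible and conservative (screened = excluded +
included).  Cohort 2 is the subset with natalizumab or fingolimod in
line 2; the arm is the line-2 drug.  Baseline tables use Welch t-tests
for continuous covariates and chi-square for categorical ones; a
paper-literal flag switches the categorical tests to per-level t-tests
on indicators, since a t-test on a multi-level distribution is not
well defined.

## Outcomes

A stay qualifies as a hospitalization iff discharge − admission > 1 day;
qualifying stays are attributed to the line whose [start, end) interval
contains the admission, and unattributed stays are excluded.  AHR is
pooled events over person-years within the stratum (not a per-patient
mean), person-time censored at line end; first-line AHR in cohort-2
analyses uses the same patients' own line-1 intervals.  CIs are exact
Poisson (Garwood, chi-square form).  "Poisson test" is implemented as
the exact conditional binomial two-sample test; weighted analyses have
non-integer events, where the package falls back to a Wald test on the
rate difference (the Wald CI is also what the difference interval
reports).  An alternative censoring choice — stopping person-time at the
first qualifying event — is deliberately not used, since the published
quantity is a rate over full line person-time.

## Adjustment

The propensity model is a logistic regression of natalizumab (vs
fingolimod) on the six covariates, categoricals one-hot with the
alphabetically first level as reference and zero-variance columns
dropped; fitted probabilities are clipped to [1e-6, 1−1e-6]; perfect
separation raises with a penalized (ridge) fallback available.
Matching is greedy 1:1 nearest neighbor without replacement, treated
patients visited in seeded random order, caliper 0.1 on the raw PS scale
(the literal published wording; a logit-scale caliper would also be
defensible), boundary inclusive, ties broken by stable order.  IPW
defaults to standard ATE weighting — reading "the inverse of the PS"
literally would weight controls incorrectly, so the literal mode is kept
only as an option — with optional stabilization and weight truncation at
the 99th percentile.  Weighted AHRs weight both events and person-time.

## Numerical and design notes

- Determinism: one global seed fans out to named SHA-256-derived
  substreams (population, emission, matching, ...), so changing one
  stage's parameters does not shift another stage's draws; two runs with
  the same configuration are byte-identical, which the manifest's
  artifact hashes verify.
- Simulation study sizes: estimator bias/recovery uses 200 replicates of
  n = 2000 patients operating on ground-truth tables (the estimators
  under test are the PS/matching/IPW/rate machinery); balance uses 5
  replicates of n = 2000; the null calibration uses 1000 replicates at
  4000 person-years per arm, the pooled first-line person-time scale of
  a cohort of a few thousand patients.  Matched estimates are compared
  to the true effect in the matched population (an ATT-flavoured
  estimand), IPW and unadjusted estimates to the true cohort-wide
  (ATE) effect, both computable exactly from the generator's
  counterfactual rates.
- The exact conditional test is mildly conservative at these event
  counts (analytic size ≈ 0.046 at the null-calibration scale), which
  the calibration check reflects.
- Degenerate inputs: empty claim streams raise; an empty cohort 2 or a
  single-arm cohort skips the comparison with a notice rather than
  failing; zero person-time raises; a zero reference rate flags the
  percent reduction as undefined.

## Known limitations

Single-level linkage keys (no phonetic name comparison — the files carry
no names); no EM estimation of m/u by default (the deterministic default
path was preferred; u is estimated empirically, m fixed); adherence
measures (PDC/MPR), discontinuation-vs-switch attribution, relapse-rate
outcomes and costs are out of scope; the generator's confounding is
log-linear and correctly specified for the fitted propensity model, so
the recovery results do not speak to model misspecification.
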