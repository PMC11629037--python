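# Methods

## The surveillance model

`phenoval` models active vaccine-safety surveillance as four coupled
procedures over a patient-linked bundle of FHIR R4 resources.

**Case detection.** A patient becomes a case candidate when some condition
record satisfies, jointly: (1) it is attached to an encounter overlapping
the study period; (2) that encounter's care setting is allowed (default
inpatient only — the setting in which a clinically significant
myocarditis/pericarditis presentation is expected to be coded); (3) its
code is in the target-diagnosis value set and its diagnosis role is not
admitting-only (admitting diagnoses are provisional); (4) at least one
supporting-evidence observation (a cardiac-workup lab such as troponin)
falls within ±7 days of the onset date; (5) the clean window holds: no
target-coded condition in the half-open interval [index − 365 d, index);
and (6) a vaccine-valueset immunization exists with diagnosis-minus-dose
offset in the closed risk window [0, 42] days. Day arithmetic is used
throughout; timestamps are truncated to days because every window is
expressed in whole days.

Decisions the detection contract leaves open, resolved here:

- **Index event**: the earliest qualifying condition per patient (ties on
  date break on condition id). One case per patient by default, since
  downstream attrition is reported patient-wise.
- **Multiple doses**: the qualifying exposure is the dose with the
  smallest non-negative in-window offset, i.e. the latest dose at or
  before the diagnosis; deterministic tie-break on immunization id.
- **Clean window is half-open**: the index day itself never disqualifies,
  because an incident diagnosis necessarily co-occurs with its own code
  (and commonly with an admitting-role duplicate the same day).
- **Insufficient lookback**: a patient whose 365-day lookback would begin
  before the observation period is excluded, not assumed clean. The
  default study start (2020-12-14) sits 366 days after the default
  observation start (2019-12-14), so under the default configuration every
  in-study index date has full lookback coverage.
- The four case-level predicates are conjunctive, so the final candidate
  set is invariant to their evaluation order; `detect(..., stage_order=…)`
  exposes the permutation, which moves only the attrition counts. This
  invariance is property-tested.

**Exchange retrieval.** Flagged cases are re-identified in the registry by
exact match on (normalized name, birth date, sex); normalization is
case-folding plus punctuation/whitespace collapse. The registry fields an
exchange actually searches on are not standardized, so this is the minimal
plausible deterministic key. A multi-match withholds the case for privacy
(the exchange cannot assert which matching patient had the suspected
event); the exclusion is symmetric by construction. Retrieved cases get a
payload assembled under per-resource-type windows: full clinical history
for AllergyIntolerance, Condition, Encounter, Immunization,
MedicationRequest and Procedure; study period only for DiagnosticReport,
DocumentReference and Observation; Location, Practitioner and Medication
only when referenced by an already-included record. A study-period
resource without a parseable date is conservatively excluded.

**Adjudication.** Two reviewers rate each retrieved case on the
five-value scale {definite, probable, possible, doubtful,
insufficient_evidence}. Agreement is final; disagreement consults a third
reviewer exactly once. `possible` is an adjudicated false positive;
`insufficient_evidence` is a distinct category excluded from the primary
PPV denominator — the two are deliberately separate enum values even
though informal usage sometimes conflates them.

**Statistics.** PPV = (definite + probable) / (all adjudicated with
sufficient evidence); the alternate convention counts
insufficient-evidence cases as false positives, so it can never exceed the
primary PPV. Intervals are Agresti–Coull with bounds clamped to [0, 1] (a
proportion estimate must be a proportion); κ is computed between the two
primary reviewers before tie-breaking, with insufficient_evidence as a
fifth category of the agreement table; the two-sample comparison is the
pooled two-proportion z test. Degenerate inputs (empty denominator,
expected agreement 1, pooled proportion 0 or 1) raise explicit
undefined-statistic errors rather than returning 0 or NaN. Reported
percentages are rounded to one decimal; underlying fractions are kept at
full precision. The formulas are implemented directly from their
definitions because the contract pins exact clamping and error behavior;
the test suite cross-checks them against statsmodels
(`proportion_confint`, `proportions_ztest`) and scikit-learn
(`cohen_kappa_score`) as independent oracles.

One known reference-value caveat: published validation summaries of this
design sometimes print a 95% CI for PPV = 14/24 of 37.3–76.9%, whereas
direct evaluation of the Agresti–Coull formula at z = 1.96 gives
38.8–75.6%. The variant or rounding behind such printed bounds is not
recoverable, so this package implements and tests the published formula
and does not assert the printed bounds anywhere.

## The synthetic cohort generator

The generator emulates the *structure* of a hospital EHR that this class
of algorithm consumes, not real disease dynamics. Each planted category
realizes exactly the temporal/setting pattern its name implies:

| category | structure | excluded at |
| --- | --- | --- |
| true_in_window | dose at v, inpatient target dx at v + U, U ~ Uniform{0..42}, lab within ±2 d, clean lookback | — (flagged) |
| duplicate_demographics | as above, plus a second patient cloning (name, birth date, sex) | retrieval multi-match |
| out_of_window | U ~ Uniform{43..120} | vaccine exposure |
| prevalent | in-window structure plus a prior target dx at index − Uniform{30..364} | clean window |
| outpatient_only | in-window structure but the target dx only on an outpatient encounter | care setting |
| unvaccinated | inpatient target dx, no immunizations | vaccine exposure |
| background | encounters/immunizations, no target dx | target diagnosis |

Offsets are uniform on their integer ranges: no latency distribution for
vaccine-associated myopericarditis is assumed, and uniform draws maximize
boundary coverage in tests. Demographic marginals default to a large US
academic health system's population mix (age bands, sex, race, ethnicity);
at n = 10,000 the generated proportions converge to within ±2 percentage
points (tested). Planted case patients are drawn as adults (18–80);
background patients follow the age marginal with event dates clamped to
birth. Names come from a seeded in-package pool and only the normalized
`name_key` is consumed downstream; non-clone (name, birth date) pairs are
forced unique so multi-matches occur exactly where planted.

Two spec-level proportions are applied as **exact rounded quotas**, not
Bernoulli draws: `insufficient_evidence_rate` selects
round(rate × n_retrievable) flagged cases whose confirmatory
DiagnosticReport is withheld (the detection-relevant lab copy remains, so
the case is still flagged but cannot be confirmed), and `truth_ppv`
selects round(ppv × n_adjudicable) of the evidence-complete retrievable
cases as latent-true. Quotas make a cohort's realized operating point
equal the requested one, which is what both the deterministic scenario
and the PPV-recovery tests require; the cost is that sampling variability
in these two quantities is not modeled. Withholding applies only to
retrievable (non-duplicate) cases because a withheld document on a
multi-match-blocked case would be unobservable.

`consort_scenario()` wraps a fixed generator configuration (64 patients,
26 in-window cases, 4 duplicate-demographic cases, withholding rate 2/26,
truth PPV 14/24, fixed seed) together with *prescribed* reviewer labels
(3 definite, 11 probable, 10 doubtful, 2 insufficient, both reviewers
agreeing). Prescribing the labels, rather than sampling them, is what
makes the fixture's classification histogram a deterministic property of
the shipped scenario instead of a property of one lucky simulator seed.

**What passing tests do and do not show.** The generator plants exactly
one structural deviation per category, codes diagnoses cleanly, and never
misses a lab that occurred. Real EHR data contain coding errors, transfers
between care settings, multi-code index events and partially documented
workups; a detection algorithm that is exact on these synthetic cohorts
(sensitivity 1.0 against planted truth, zero false flags) establishes the
correctness of the rule logic, not the clinical operating characteristics
of the phenotype, which can only come from chart-reviewed validation on
real data.

## The reviewer simulator

Reviewers are parameterized by `sensitivity_to_truth` (default 0.9: the
probability of rating a latent-true case positive, and a latent-false case
negative) and `agreement_rate` (default 0.85: the probability reviewer 2
adopts reviewer 1's label; otherwise reviewer 2 redraws independently, so
raw observed agreement exceeds the parameter by the chance-match term —
the tested relation is agree ≈ a + (1 − a)·(s² + (1 − s)²)/2). Defaults
were picked once to land κ in the "substantial agreement" band typical of
two-clinician chart review. Within the positive (definite/probable) and
negative (possible/doubtful) pairs the label is uniform; only the union
affects PPV. Withheld-evidence cases are rated insufficient by both
reviewers deterministically. The tie-breaking third reviewer draws
independently from the same scheme and is not shown the first two labels.

## Problem sizes and determinism

The shipped scenario (64 patients) runs in well under a second; the mixed
property-testing cohort uses 1,000 patients across all seven categories,
and statistical calibration (Agresti–Coull coverage) uses 10,000 binomial
replicates per grid point at p ∈ {0.2, 0.5, 0.8}, n ∈ {20, 50} — sizes at
which every Monte-Carlo tolerance in the suite is comfortably resolved.
All randomness flows through `numpy.random.default_rng` seeded from the
cohort spec or CLI `--seed`; identical spec + seed yields byte-identical
NDJSON output (tested), and every CLI command writes a manifest with seed
and content hashes.

## CLI

The library functions are the primary interface; the `phenoval` console
script exposes `generate`, `detect` and `run-all` as thin wrappers for
shell use, with `run-all` writing each intermediate artifact
(candidates.csv, attrition.json, reviews.csv, adjudications.csv,
report.json/md) so the retrieval/adjudication/statistics stages need no
separate subcommands. Exit codes: 0 success, 1 configuration error,
2 data error.
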