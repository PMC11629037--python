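# phenoval

Rules-based computable-phenotype detection and validation statistics for
postvaccination adverse-event surveillance on FHIR R4 electronic health
record (EHR) data.

Active vaccine-safety surveillance programs distribute *computable
phenotypes* — machine-executable rule sets over EHR data — to partner
health systems, which run them locally and report flagged cases for
clinical validation. `phenoval` implements one such pipeline end to end
for a myocarditis/pericarditis phenotype after COVID-19 vaccination, for
epidemiologists and informaticists who need to test, audit or extend this
class of algorithm without access to protected health data:

- **Detection** (`phenotype_engine`): ordered filter stages over a bundle
  of FHIR resources — encounters in the study period (2020-12-14 to
  2023-04-28 by default), inpatient care setting, a target-diagnosis code
  match (admitting-only diagnoses ignored), supporting lab evidence within
  ±7 days of the index diagnosis, a 365-day *clean window* with no prior
  qualifying diagnosis (so the case is incident), and a vaccine exposure
  such that the diagnosis falls in the 0–42-day *risk window* after a
  dose. Every stage's entering/surviving counts are recorded in a
  CONSORT-style attrition report.
- **Exchange retrieval** (`exchange_retrieval`): demographic matching of
  flagged cases against the registry on (normalized name, birth date,
  sex); cases matching multiple patients are withheld for privacy;
  retrieved cases get a validation payload assembled with per-resource-type
  date windows (full history for Condition/Encounter/Immunization/…,
  study period for Observation/DiagnosticReport/DocumentReference,
  linked-only for Location/Practitioner/Medication).
- **Adjudication** (`adjudication`): two-reviewer bookkeeping with the
  conventional diagnostic-certainty scale (definite / probable / possible /
  doubtful, plus insufficient-evidence), third-reviewer tie-breaking, and a
  truth-driven reviewer simulator.
- **Validation statistics** (`validation_stats`): positive predictive
  value under both denominator conventions, Agresti–Coull binomial
  intervals, Cohen κ interrater agreement, and a pooled two-sample
  proportion z test. With TP = definite + probable and FP = possible +
  doubtful:

  PPV = TP / (TP + FP), PPV_alt = TP / (TP + FP + n_insufficient)

  and the Agresti–Coull 95% interval uses ñ = n + z², p̃ = (x + z²/2)/ñ,
  p̃ ± z·√(p̃(1−p̃)/ñ), clamped to [0, 1].
- **Synthetic cohorts** (`synthetic_cohort`): a seeded generator planting
  patients of known category — in-window incident inpatient cases,
  out-of-window, prevalent, outpatient-only, unvaccinated,
  duplicate-demographics — each carrying a truth label naming the stage
  that should admit or exclude it, plus a deterministic scenario
  (`consort_scenario`) exercising the full attrition flow.

## Worked example

```python
import phenoval as pv

fx = pv.consort_scenario()
res = pv.run_pipeline(fx.bundle, fx.truth_labels, prescribed_reviews=fx.reviews)
for s in res.attrition.stages:
    print(f"{s.stage_name:28s} {s.entering_count:4d} -> {s.surviving_count}")
print(res.report["classification_counts"])
print("PPV", res.report["ppv"]["point_pct"],
      "alt", res.report["ppv_alternate"]["point_pct"],
      "insufficient %", res.report["insufficient_evidence_pct"])
```

prints

```
study_period_encounters       113 -> 91
care_setting                   91 -> 41
target_diagnosis               51 -> 30
supporting_evidence            30 -> 30
clean_window                   30 -> 30
vaccine_exposure               30 -> 30
one_case_per_patient           30 -> 30
exchange_retrieval             30 -> 26
sufficient_evidence            26 -> 24
{'definite': 3, 'probable': 11, 'possible': 0, 'doubtful': 10, 'insufficient_evidence': 2}
PPV 58.3 alt 53.8 insufficient % 7.7
```

Thirty cases survive detection; four are excluded because their
demographics match two registry patients (the multi-match privacy rule);
two of the 26 retrieved lack the documentation needed for a determination;
of the 24 adjudicated, 14 (definite + probable) are true positives, giving
a primary PPV of 58.3% (alternate 53.8% when the insufficient-evidence
cases count as false positives).

The same pipeline is available from a shell:

```bash
phenoval generate --n-patients 200 --n-true-cases 10 --seed 7 --out-dir cohort/
phenoval detect --bundle-dir cohort/ --out-dir detected/
phenoval run-all --bundle-dir cohort/ --seed 7 --out-dir run/
phenoval run-all --consort-fixture --out-dir fixture-run/
```

## Limitations

The exchange transport itself (network protocol, security) is out of
scope — retrieval is simulated against the local registry. Shipped value
sets are documented stand-ins, fully overridable via YAML/CSV config.
Clinical judgment is abstracted to latent truth labels; see
`docs/methods.md` for the model, parameter defaults and known limitations.
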