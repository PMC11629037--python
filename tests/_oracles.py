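"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the staged/indexed code paths of the package:
every (patient, condition, immunization) triple is tested directly against
the phenotype predicates, and value-set membership is a literal linear scan.
"""

from datetime import timedelta

from phenoval.ehr_model import ConceptRole, DiagnosisRole, valuesets_by_role


def vs_match(valuesets, coding):
    """Linear-scan value-set membership with explicit prefix semantics."""
    for vs in valuesets:
        for entry in vs.entries:
            if entry.system != coding.system:
                continue
            if entry.prefix:
                if coding.code[:len(entry.code)] == entry.code:
                    return True
            elif coding.code == entry.code:
                return True
    return False


def event_failures(bundle, valuesets, config, cond):
    """The set of conjunctive predicates a single condition event fails.

    Returns None when the condition is not an event at all (no qualifying
    encounter in the study period / allowed care setting).
    """
    by_role = valuesets_by_role(valuesets)
    target = by_role[ConceptRole.target_diagnosis]
    vaccine = by_role[ConceptRole.exposure_vaccine]
    evidence = by_role[ConceptRole.supporting_evidence]

    enc = next((e for e in bundle.encounters if e.encounter_id == cond.encounter_id), None)
    if enc is None:
        return None
    if not (enc.start_date <= config.study_end and enc.end_date >= config.study_start):
        return None
    if enc.care_setting not in config.care_settings:
        return None

    failures = set()
    ok_target = vs_match(target, cond.code)
    if config.exclude_admitting_only and cond.diagnosis_role == DiagnosisRole.admitting:
        ok_target = False
    if not (config.study_start <= cond.onset_date <= config.study_end):
        ok_target = False
    if not ok_target:
        failures.add("target_diagnosis")

    if config.require_supporting_evidence:
        w = timedelta(days=config.supporting_evidence_window_days)
        has_evidence = any(
            o.patient_id == cond.patient_id and vs_match(evidence, o.code)
            and cond.onset_date - w <= o.effective_date <= cond.onset_date + w
            for o in bundle.observations)
        if not has_evidence:
            failures.add("supporting_evidence")

    window_start = cond.onset_date - timedelta(days=config.clean_window_days)
    clean = window_start >= config.observation_start and not any(
        c.patient_id == cond.patient_id
        and window_start <= c.onset_date < cond.onset_date
        and vs_match(target, c.code)
        for c in bundle.conditions)
    if not clean:
        failures.add("clean_window")

    exposed = any(
        i.patient_id == cond.patient_id and vs_match(vaccine, i.code)
        and config.risk_window.lower
        <= (cond.onset_date - i.administration_date).days
        <= config.risk_window.upper
        for i in bundle.immunizations)
    if not exposed:
        failures.add("vaccine_exposure")
    return failures


def brute_force_candidates(bundle, valuesets, config):
    """All qualifying (patient, index date) pairs, earliest event per patient."""
    best = {}
    for cond in bundle.conditions:
        failures = event_failures(bundle, valuesets, config, cond)
        if failures != set():
            continue
        cur = best.get(cond.patient_id)
        if cur is None or (cond.onset_date, cond.condition_id) < (cur.onset_date, cur.condition_id):
            best[cond.patient_id] = cond
    return {(c.patient_id, c.onset_date) for c in best.values()}


def patient_stage_failures(bundle, valuesets, config, patient_id):
    """Per-patient view: failure sets of every event the patient has.

    An empty list means the patient has no candidate event at all (excluded
    by the encounter-level stages); an empty set inside means a fully
    qualifying event.
    """
    out = []
    for cond in bundle.conditions:
        if cond.patient_id != patient_id:
            continue
        failures = event_failures(bundle, valuesets, config, cond)
        if failures is not None:
            out.append(failures)
    return out
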