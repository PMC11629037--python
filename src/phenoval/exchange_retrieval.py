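"""Simulated health-information-exchange retrieval of flagged cases.

Retrieval locates each flagged case in the registry by exact demographic
match on (normalized name, birth date, sex).  When the demographics match
more than one registry patient the case is withheld for privacy — the
exchange cannot confirm which of the matching patients had the suspected
adverse event — and when the match is unique the per-case validation
payload is assembled with per-resource-type date windows: some resource
types ship full clinical history, some only the study period, and
directory-style resources (Location, Practitioner, Medication) only when
referenced by an included record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .ehr_model import EhrBundle, PatientRecord, parse_day, patient_to_fhir
from .phenotype_engine import AttritionReport, CaseCandidate


class MatchStatus(str, Enum):
    unique = "unique"
    multiple = "multiple"
    none = "none"


@dataclass(frozen=True)
class MatchResult:
    patient_id: str
    match_status: MatchStatus
    matched_registry_ids: tuple[str, ...]
    reason: str = ""


class WindowRule(str, Enum):
    full_history = "full_history"
    study_period = "study_period"
    linked_only = "linked_only"
    single = "single"


RESOURCE_WINDOWS: dict[str, WindowRule] = {
    "Patient": WindowRule.single,
    "AllergyIntolerance": WindowRule.full_history,
    "Condition": WindowRule.full_history,
    "Encounter": WindowRule.full_history,
    "Immunization": WindowRule.full_history,
    "MedicationRequest": WindowRule.full_history,
    "Procedure": WindowRule.full_history,
    "DiagnosticReport": WindowRule.study_period,
    "DocumentReference": WindowRule.study_period,
    "Observation": WindowRule.study_period,
    "Location": WindowRule.linked_only,
    "Practitioner": WindowRule.linked_only,
    "Medication": WindowRule.linked_only,
}

_DATE_KEYS = ("effectiveDateTime", "date", "occurrenceDateTime", "authoredOn",
              "performedDateTime", "onsetDateTime", "recordedDate")


@dataclass
class CasePayload:
    """The per-case record collection shipped for clinical validation."""

    case_id: str
    patient: PatientRecord
    encounters: list = field(default_factory=list)
    conditions: list = field(default_factory=list)
    immunizations: list = field(default_factory=list)
    observations: list = field(default_factory=list)
    passthrough: dict[str, list[dict]] = field(default_factory=dict)


def _demographic_key(name_key: str, birth_date: date, sex: str) -> tuple:
    return (name_key, birth_date.isoformat(), str(sex))


def match_patient(demographics: Mapping[str, str],
                  registry: Iterable[PatientRecord]) -> MatchResult:
    """Exact-match demographics against the registry.

    ``demographics`` must provide name_key, birth_date (ISO) and sex;
    anything missing yields status none with an explanatory reason rather
    than a partial match.
    """
    pid = str(demographics.get("patient_id", ""))
    missing = [k for k in ("name_key", "birth_date", "sex") if not demographics.get(k)]
    if missing:
        return MatchResult(pid, MatchStatus.none, (),
                           reason=f"incomplete demographics: missing {', '.join(missing)}")
    key = (demographics["name_key"], str(demographics["birth_date"])[:10],
           str(demographics["sex"]))
    matched = tuple(sorted(
        p.patient_id for p in registry
        if _demographic_key(p.name_key, p.birth_date, p.sex.value) == key))
    if len(matched) == 1:
        return MatchResult(pid, MatchStatus.unique, matched)
    if len(matched) >= 2:
        return MatchResult(pid, MatchStatus.multiple, matched,
                           reason="demographics match multiple registry patients")
    return MatchResult(pid, MatchStatus.none, (), reason="no registry match")


def _record_date(obj: Mapping) -> Optional[date]:
    for key in _DATE_KEYS:
        if key in obj:
            try:
                return parse_day(obj[key])
            except (ValueError, TypeError):
                return None
    period = obj.get("period") or {}
    if "start" in period:
        try:
            return parse_day(period["start"])
        except (ValueError, TypeError):
            return None
    return None


def _collect_references(obj) -> set[str]:
    refs: set[str] = set()
    if isinstance(obj, dict):
        ref = obj.get("reference")
        if isinstance(ref, str):
            refs.add(ref)
        for v in obj.values():
            refs |= _collect_references(v)
    elif isinstance(obj, list):
        for item in obj:
            refs |= _collect_references(item)
    return refs


def assemble_payload(candidate: CaseCandidate, bundle: EhrBundle,
                     study_period: tuple[date, date]) -> CasePayload:
    """Build the validation payload for a uniquely matched case.

    Typed clinical records for the patient are included per their resource
    window; pass-through resources are filtered the same way (a study-period
    resource without a parseable date is conservatively excluded), and
    linked-only resources are included iff something already in the payload
    references them.
    """
    start, end = study_period
    pid = candidate.patient_id
    patient = next(p for p in bundle.patients if p.patient_id == pid)
    payload = CasePayload(case_id=pid, patient=patient)
    payload.encounters = [e for e in bundle.encounters if e.patient_id == pid]
    payload.conditions = [c for c in bundle.conditions if c.patient_id == pid]
    payload.immunizations = [i for i in bundle.immunizations if i.patient_id == pid]
    payload.observations = [o for o in bundle.observations if o.patient_id == pid
                            and start <= o.effective_date <= end]

    linked_pool: dict[str, list[dict]] = {}
    for rtype, lines in bundle.passthrough.items():
        rule = RESOURCE_WINDOWS.get(rtype, WindowRule.full_history)
        for line in lines:
            obj = json.loads(line)
            if rule == WindowRule.linked_only:
                linked_pool.setdefault(rtype, []).append(obj)
                continue
            subject = obj.get("subject") or obj.get("patient") or {}
            if subject.get("reference") != f"Patient/{pid}":
                continue
            if rule == WindowRule.study_period:
                day = _record_date(obj)
                if day is None or not start <= day <= end:
                    continue
            payload.passthrough.setdefault(rtype, []).append(obj)

    refs: set[str] = set()
    for objs in payload.passthrough.values():
        for obj in objs:
            refs |= _collect_references(obj)
    for rtype, objs in linked_pool.items():
        included = [o for o in objs if f"{rtype}/{o.get('id')}" in refs]
        if included:
            payload.passthrough[rtype] = included
    return payload


def retrieve_all(
    candidates: Sequence[CaseCandidate],
    bundle: EhrBundle,
    study_period: tuple[date, date],
    report: Optional[AttritionReport] = None,
) -> tuple[list[CasePayload], list[MatchResult], AttritionReport]:
    """Match every candidate, assemble payloads for the unique matches.

    Multi-match and no-match exclusions are counted separately in the
    attrition report (appended to ``report`` when given).
    """
    report = report if report is not None else AttritionReport()
    results: list[MatchResult] = []
    payloads: list[CasePayload] = []
    for cand in candidates:
        demo = dict(cand.demographics)
        demo["patient_id"] = cand.patient_id
        result = match_patient(demo, bundle.patients)
        results.append(result)
        if result.match_status == MatchStatus.unique:
            payloads.append(assemble_payload(cand, bundle, study_period))
    n_multi = sum(1 for r in results if r.match_status == MatchStatus.multiple)
    n_none = sum(1 for r in results if r.match_status == MatchStatus.none)
    report.add("exchange_retrieval", len(candidates), len(payloads), "cases",
               multi_match_exclusions=n_multi, no_match_exclusions=n_none)
    return payloads, results, report


def payload_to_ndjson(payload: CasePayload, directory) -> None:
    """Write one case payload as a directory of NDJSON files."""
    from pathlib import Path
    from .ehr_model import (condition_to_fhir, encounter_to_fhir,
                            immunization_to_fhir, observation_to_fhir)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def dump(objs, name):
        if objs:
            (directory / f"{name}.ndjson").write_text(
                "".join(json.dumps(o, sort_keys=True, separators=(",", ":")) + "\n"
                        for o in objs))

    dump([patient_to_fhir(payload.patient)], "Patient")
    dump([encounter_to_fhir(e) for e in payload.encounters], "Encounter")
    dump([condition_to_fhir(c) for c in payload.conditions], "Condition")
    dump([immunization_to_fhir(i) for i in payload.immunizations], "Immunization")
    dump([observation_to_fhir(o) for o in payload.observations], "Observation")
    for rtype, objs in payload.passthrough.items():
        dump(objs, rtype)
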