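"""Domain types for EHR content plus FHIR R4 NDJSON and value-set I/O.

The pipeline operates on a small interpreted subset of FHIR R4: Patient,
Encounter, Condition, Immunization and Observation are parsed into typed
records; every other resource type (DiagnosticReport, DocumentReference,
Procedure, ...) is carried through verbatim so that retrieval payloads can
still ship it to reviewers.  Dates are handled at day granularity throughout
because every temporal rule in the phenotype (risk window, clean window,
evidence window) is expressed in whole days.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

from .errors import ConfigError, DataError

# Resource types carried through without interpretation, in the order their
# files are conventionally written.
PASSTHROUGH_TYPES = (
    "AllergyIntolerance",
    "DiagnosticReport",
    "DocumentReference",
    "MedicationRequest",
    "Procedure",
    "Location",
    "Practitioner",
    "Medication",
)

TYPED_RESOURCES = ("Patient", "Encounter", "Condition", "Immunization", "Observation")

ICD10CM = "http://hl7.org/fhir/sid/icd-10-cm"
LOINC = "http://loinc.org"
CVX = "http://hl7.org/fhir/sid/cvx"


class Sex(str, Enum):
    male = "male"
    female = "female"
    other = "other"


class Race(str, Enum):
    white = "white"
    black = "black"
    asian_pacific = "asian_pacific"
    american_indian_alaska_native = "american_indian_alaska_native"
    other = "other"
    unknown = "unknown"
    declined = "declined"


class Ethnicity(str, Enum):
    hispanic = "hispanic"
    non_hispanic = "non_hispanic"
    unknown = "unknown"


class CareSetting(str, Enum):
    inpatient = "inpatient"
    outpatient = "outpatient"
    emergency = "emergency"
    other = "other"


class DiagnosisRole(str, Enum):
    admitting = "admitting"
    final = "final"
    other = "other"


class ConceptRole(str, Enum):
    target_diagnosis = "target_diagnosis"
    supporting_evidence = "supporting_evidence"
    exposure_vaccine = "exposure_vaccine"


_NAME_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Case-fold a display name, strip punctuation, collapse whitespace.

    The result is the demographic matching key used by exchange retrieval;
    nothing else in the pipeline consumes patient names.
    """
    return _WS.sub(" ", _NAME_PUNCT.sub(" ", raw.casefold())).strip()


def parse_day(value: str) -> date:
    """Parse a FHIR date or dateTime to a calendar day (timestamps truncated)."""
    return date.fromisoformat(str(value)[:10])


@dataclass(frozen=True)
class Coding:
    system: str
    code: str


@dataclass(frozen=True)
class ValueSetEntry:
    system: str
    code: str
    prefix: bool = False

    def matches(self, coding: Coding) -> bool:
        if self.system != coding.system:
            return False
        if self.prefix:
            return coding.code.startswith(self.code)
        return coding.code == self.code


@dataclass
class ValueSet:
    """A named list of coded concepts with a role in the phenotype.

    Matching is exact, case-sensitive (system, code) equality after leading /
    trailing whitespace has been trimmed at load time; entries flagged
    ``prefix`` match any code sharing their prefix, which is how ICD-10 code
    families such as I40.* are conventionally written in code lists.
    """

    name: str
    role: ConceptRole
    entries: list[ValueSetEntry]
    description: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.system, e.code)
            if key in seen:
                raise ConfigError(
                    f"value set {self.name!r}: duplicate entry ({e.system!r}, {e.code!r})"
                )
            seen.add(key)

    def contains(self, coding: Coding) -> bool:
        return any(e.matches(coding) for e in self.entries)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    birth_date: date
    sex: Sex
    race: Race
    ethnicity: Ethnicity
    name_key: str


@dataclass(frozen=True)
class EncounterRecord:
    encounter_id: str
    patient_id: str
    care_setting: CareSetting
    start_date: date
    end_date: date


@dataclass(frozen=True)
class ConditionRecord:
    condition_id: str
    patient_id: str
    code: Coding
    onset_date: date
    diagnosis_role: DiagnosisRole = DiagnosisRole.final
    encounter_id: Optional[str] = None


@dataclass(frozen=True)
class ImmunizationRecord:
    immunization_id: str
    patient_id: str
    code: Coding
    administration_date: date


@dataclass(frozen=True)
class ObservationRecord:
    observation_id: str
    patient_id: str
    code: Coding
    effective_date: date
    value: Optional[float] = None


@dataclass(frozen=True)
class RejectedLine:
    resource_type: str
    line_number: int
    reason: str
    raw: str


@dataclass
class EhrBundle:
    """A patient-linked collection of typed records plus verbatim pass-throughs.

    ``passthrough`` maps a FHIR resource-type name to the raw NDJSON lines of
    that type; the lines are preserved byte-for-byte on round trip.  ``rejects``
    collects input lines that failed validation on read; it is bookkeeping, not
    content, and is excluded from equality.
    """

    patients: list[PatientRecord] = field(default_factory=list)
    encounters: list[EncounterRecord] = field(default_factory=list)
    conditions: list[ConditionRecord] = field(default_factory=list)
    immunizations: list[ImmunizationRecord] = field(default_factory=list)
    observations: list[ObservationRecord] = field(default_factory=list)
    passthrough: dict[str, list[str]] = field(default_factory=dict)
    rejects: list[RejectedLine] = field(default_factory=list, compare=False)

    def patient_ids(self) -> set[str]:
        return {p.patient_id for p in self.patients}

    def sorted_copy(self) -> "EhrBundle":
        return EhrBundle(
            patients=sorted(self.patients, key=lambda r: r.patient_id),
            encounters=sorted(self.encounters, key=lambda r: r.encounter_id),
            conditions=sorted(self.conditions, key=lambda r: r.condition_id),
            immunizations=sorted(self.immunizations, key=lambda r: r.immunization_id),
            observations=sorted(self.observations, key=lambda r: r.observation_id),
            passthrough={
                t: sorted(lines, key=_passthrough_sort_key)
                for t, lines in self.passthrough.items()
                if lines
            },
            rejects=list(self.rejects),
        )


def _passthrough_sort_key(line: str) -> str:
    try:
        return str(json.loads(line).get("id", ""))
    except json.JSONDecodeError:
        return ""


# ---------------------------------------------------------------------------
# FHIR (de)serialization for the interpreted resource types
# ---------------------------------------------------------------------------

_RACE_EXT = "urn:phenoval:race"
_ETHNICITY_EXT = "urn:phenoval:ethnicity"

_GENDER_TO_SEX = {"male": Sex.male, "female": Sex.female, "other": Sex.other, "unknown": Sex.other}
_SETTING_TO_CLASS = {
    CareSetting.inpatient: "IMP",
    CareSetting.outpatient: "AMB",
    CareSetting.emergency: "EMER",
    CareSetting.other: "OTH",
}
_CLASS_TO_SETTING = {v: k for k, v in _SETTING_TO_CLASS.items()}
_ROLE_TO_CODE = {DiagnosisRole.admitting: "AD", DiagnosisRole.final: "DD", DiagnosisRole.other: "OT"}
_CODE_TO_ROLE = {v: k for k, v in _ROLE_TO_CODE.items()}
_DIAGNOSIS_ROLE_SYSTEM = "http://terminology.hl7.org/CodeSystem/diagnosis-role"


def _codeable(coding: Coding) -> dict:
    return {"coding": [{"system": coding.system, "code": coding.code}]}


def _first_coding(codeable: Mapping) -> Coding:
    coding = (codeable or {}).get("coding") or []
    if not coding:
        raise ValueError("empty code")
    return Coding(system=str(coding[0].get("system", "")).strip(), code=str(coding[0]["code"]).strip())


def patient_to_fhir(p: PatientRecord) -> dict:
    return {
        "resourceType": "Patient",
        "id": p.patient_id,
        "birthDate": p.birth_date.isoformat(),
        "gender": p.sex.value,
        "name": [{"text": p.name_key}],
        "extension": [
            {"url": _RACE_EXT, "valueCode": p.race.value},
            {"url": _ETHNICITY_EXT, "valueCode": p.ethnicity.value},
        ],
    }


def patient_from_fhir(obj: Mapping) -> PatientRecord:
    ext = {e.get("url"): e.get("valueCode") for e in obj.get("extension", [])}
    names = obj.get("name") or [{}]
    return PatientRecord(
        patient_id=str(obj["id"]),
        birth_date=parse_day(obj["birthDate"]),
        sex=_GENDER_TO_SEX.get(obj.get("gender", "unknown"), Sex.other),
        race=Race(ext.get(_RACE_EXT, "unknown")),
        ethnicity=Ethnicity(ext.get(_ETHNICITY_EXT, "unknown")),
        name_key=normalize_name(names[0].get("text", "")),
    )


def encounter_to_fhir(e: EncounterRecord) -> dict:
    return {
        "resourceType": "Encounter",
        "id": e.encounter_id,
        "subject": {"reference": f"Patient/{e.patient_id}"},
        "class": {"system": "http://terminology.hl7.org/CodeSystem/v3-ActCode",
                  "code": _SETTING_TO_CLASS[e.care_setting]},
        "period": {"start": e.start_date.isoformat(), "end": e.end_date.isoformat()},
    }


def encounter_from_fhir(obj: Mapping) -> EncounterRecord:
    period = obj.get("period") or {}
    start = parse_day(period["start"])
    end = parse_day(period.get("end", period["start"]))
    if end < start:
        raise ValueError("encounter end before start")
    return EncounterRecord(
        encounter_id=str(obj["id"]),
        patient_id=_ref_id(obj["subject"]),
        care_setting=_CLASS_TO_SETTING.get((obj.get("class") or {}).get("code"), CareSetting.other),
        start_date=start,
        end_date=end,
    )


def condition_to_fhir(c: ConditionRecord) -> dict:
    out = {
        "resourceType": "Condition",
        "id": c.condition_id,
        "subject": {"reference": f"Patient/{c.patient_id}"},
        "code": _codeable(c.code),
        "onsetDateTime": c.onset_date.isoformat(),
        "category": [{"coding": [{"system": _DIAGNOSIS_ROLE_SYSTEM,
                                  "code": _ROLE_TO_CODE[c.diagnosis_role]}]}],
    }
    if c.encounter_id is not None:
        out["encounter"] = {"reference": f"Encounter/{c.encounter_id}"}
    return out


def condition_from_fhir(obj: Mapping) -> ConditionRecord:
    role = DiagnosisRole.other
    for cat in obj.get("category", []):
        for coding in cat.get("coding", []):
            if coding.get("system") == _DIAGNOSIS_ROLE_SYSTEM:
                role = _CODE_TO_ROLE.get(coding.get("code"), DiagnosisRole.other)
    enc = obj.get("encounter")
    return ConditionRecord(
        condition_id=str(obj["id"]),
        patient_id=_ref_id(obj["subject"]),
        code=_first_coding(obj["code"]),
        onset_date=parse_day(obj["onsetDateTime"]),
        diagnosis_role=role,
        encounter_id=_ref_id(enc) if enc else None,
    )


def immunization_to_fhir(i: ImmunizationRecord) -> dict:
    return {
        "resourceType": "Immunization",
        "id": i.immunization_id,
        "patient": {"reference": f"Patient/{i.patient_id}"},
        "vaccineCode": _codeable(i.code),
        "occurrenceDateTime": i.administration_date.isoformat(),
    }


def immunization_from_fhir(obj: Mapping) -> ImmunizationRecord:
    return ImmunizationRecord(
        immunization_id=str(obj["id"]),
        patient_id=_ref_id(obj["patient"]),
        code=_first_coding(obj["vaccineCode"]),
        administration_date=parse_day(obj["occurrenceDateTime"]),
    )


def observation_to_fhir(o: ObservationRecord) -> dict:
    out = {
        "resourceType": "Observation",
        "id": o.observation_id,
        "subject": {"reference": f"Patient/{o.patient_id}"},
        "code": _codeable(o.code),
        "effectiveDateTime": o.effective_date.isoformat(),
    }
    if o.value is not None:
        out["valueQuantity"] = {"value": o.value}
    return out


def observation_from_fhir(obj: Mapping) -> ObservationRecord:
    vq = obj.get("valueQuantity") or {}
    return ObservationRecord(
        observation_id=str(obj["id"]),
        patient_id=_ref_id(obj["subject"]),
        code=_first_coding(obj["code"]),
        effective_date=parse_day(obj["effectiveDateTime"]),
        value=float(vq["value"]) if "value" in vq else None,
    )


def _ref_id(ref: Mapping) -> str:
    return str(ref["reference"]).split("/", 1)[1]


_FROM_FHIR = {
    "Patient": patient_from_fhir,
    "Encounter": encounter_from_fhir,
    "Condition": condition_from_fhir,
    "Immunization": immunization_from_fhir,
    "Observation": observation_from_fhir,
}
_TO_FHIR = {
    "Patient": patient_to_fhir,
    "Encounter": encounter_to_fhir,
    "Condition": condition_to_fhir,
    "Immunization": immunization_to_fhir,
    "Observation": observation_to_fhir,
}
_BUNDLE_ATTR = {
    "Patient": "patients",
    "Encounter": "encounters",
    "Condition": "conditions",
    "Immunization": "immunizations",
    "Observation": "observations",
}


# ---------------------------------------------------------------------------
# NDJSON reading / writing
# ---------------------------------------------------------------------------

def read_bundle(paths: Mapping[str, Union[str, Path]]) -> EhrBundle:
    """Load an EHR bundle from NDJSON files, one file per resource type.

    Lines that fail to parse or validate are collected on ``bundle.rejects``
    with a reason rather than silently dropped; a clinical record whose
    patient reference does not resolve is likewise rejected so that the
    returned bundle always has referential integrity.
    """
    if "Patient" not in paths:
        raise DataError("a Patient NDJSON file is required")
    bundle = EhrBundle()
    deferred: list[tuple[str, int, str, object]] = []
    for rtype, path in paths.items():
        path = Path(path)
        if not path.exists():
            if rtype == "Patient":
                raise DataError(f"missing Patient file: {path}")
            bundle.rejects.append(RejectedLine(rtype, 0, f"missing file: {path}", ""))
            continue
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                bundle.rejects.append(RejectedLine(rtype, lineno, f"malformed JSON: {exc}", line))
                continue
            actual = obj.get("resourceType")
            if actual != rtype:
                bundle.rejects.append(
                    RejectedLine(rtype, lineno, f"unexpected resourceType {actual!r}", line))
                continue
            if rtype in _FROM_FHIR:
                try:
                    record = _FROM_FHIR[rtype](obj)
                except (KeyError, ValueError, TypeError) as exc:
                    bundle.rejects.append(
                        RejectedLine(rtype, lineno, f"schema violation: {exc}", line))
                    continue
                if rtype == "Patient":
                    bundle.patients.append(record)
                else:
                    deferred.append((rtype, lineno, line, record))
            else:
                bundle.passthrough.setdefault(rtype, []).append(line)
    known = bundle.patient_ids()
    for rtype, lineno, line, record in deferred:
        if record.patient_id not in known:
            bundle.rejects.append(
                RejectedLine(rtype, lineno, f"unknown patient_id {record.patient_id!r}", line))
        else:
            getattr(bundle, _BUNDLE_ATTR[rtype]).append(record)
    return bundle


def read_bundle_dir(directory: Union[str, Path]) -> EhrBundle:
    """Load a bundle from a directory of ``<ResourceType>.ndjson`` files."""
    directory = Path(directory)
    paths = {p.stem: p for p in sorted(directory.glob("*.ndjson"))}
    return read_bundle(paths)


def _dumps(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def write_bundle(bundle: EhrBundle, directory: Union[str, Path]) -> dict[str, Path]:
    """Write a bundle as NDJSON, one file per resource type, sorted by id.

    The five interpreted types are always written (possibly as empty files);
    pass-through types are written verbatim only when present.  Sorting makes
    output deterministic so identical bundles yield identical bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    sb = bundle.sorted_copy()
    for rtype in TYPED_RESOURCES:
        records = getattr(sb, _BUNDLE_ATTR[rtype])
        path = directory / f"{rtype}.ndjson"
        path.write_text("".join(_dumps(_TO_FHIR[rtype](r)) + "\n" for r in records))
        written[rtype] = path
    for rtype, lines in sb.passthrough.items():
        path = directory / f"{rtype}.ndjson"
        path.write_text("".join(line + "\n" for line in lines))
        written[rtype] = path
    return written


# ---------------------------------------------------------------------------
# Value-set configuration
# ---------------------------------------------------------------------------

def _build_valueset(name: str, role: str, entries: Iterable[Mapping], description: str) -> ValueSet:
    try:
        role_enum = ConceptRole(role)
    except ValueError:
        raise ConfigError(f"value set {name!r}: unknown role {role!r}") from None
    vs_entries = [
        ValueSetEntry(
            system=str(e["system"]).strip(),
            code=str(e["code"]).strip(),
            prefix=_truthy(e.get("prefix", False)),
        )
        for e in entries
    ]
    return ValueSet(name=name, role=role_enum, entries=vs_entries, description=description)


def _truthy(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    return bool(value)


def load_valuesets(path: Union[str, Path]) -> list[ValueSet]:
    """Load value sets from a YAML or CSV file.

    YAML layout: a top-level ``valuesets`` list of {name, role, description,
    entries: [{system, code, prefix}]}.  CSV layout: one row per entry with
    columns name, role, system, code, prefix_flag, description.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        sets = _valuesets_from_yaml(path.read_text())
    else:
        sets = _valuesets_from_csv(path.read_text())
    present = {vs.role for vs in sets}
    missing = set(ConceptRole) - present
    if missing:
        raise ConfigError(
            "value-set config must define every role; missing: "
            + ", ".join(sorted(r.value for r in missing)))
    return sets


def _valuesets_from_yaml(text: str) -> list[ValueSet]:
    doc = yaml.safe_load(text) or {}
    return [
        _build_valueset(
            name=str(item["name"]),
            role=str(item["role"]),
            entries=item.get("entries", []),
            description=str(item.get("description", "")),
        )
        for item in doc.get("valuesets", [])
    ]


def _valuesets_from_csv(text: str) -> list[ValueSet]:
    grouped: dict[str, dict] = {}
    for row in csv.DictReader(text.splitlines()):
        g = grouped.setdefault(row["name"], {"role": row["role"],
                                             "description": row.get("description", ""),
                                             "entries": []})
        g["entries"].append({"system": row["system"], "code": row["code"],
                             "prefix": row.get("prefix_flag", "")})
    return [
        _build_valueset(name, g["role"], g["entries"], g["description"])
        for name, g in grouped.items()
    ]


def default_valuesets() -> list[ValueSet]:
    """The value sets shipped with the package.

    These are editable stand-ins covering the myocarditis/pericarditis ICD-10
    family, a cardiac-workup evidence panel (troponin, natriuretic peptides)
    and the CVX codes of the US-authorized COVID-19 vaccines; real deployments
    substitute their curated code lists via ``load_valuesets``.
    """
    text = resources.files("phenoval.data").joinpath("default_valuesets.yaml").read_text()
    return _valuesets_from_yaml(text)


def valuesets_by_role(valuesets: Iterable[ValueSet]) -> dict[ConceptRole, list[ValueSet]]:
    by_role: dict[ConceptRole, list[ValueSet]] = {}
    for vs in valuesets:
        by_role.setdefault(vs.role, []).append(vs)
    return by_role
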