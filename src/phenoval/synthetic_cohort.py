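"""Seeded synthetic EHR cohort generator with controlled ground truth.

The generator emulates a hospital EHR over a vaccine surveillance study
period (default 2020-12-14 through 2023-04-28 with lookback from
2019-12-14): demographics with realistic marginals, COVID-19 immunization
records, incident and prevalent myocarditis/pericarditis diagnoses inside
and outside the postvaccination risk window, inpatient vs outpatient care
settings, supporting-evidence lab observations, and duplicate-demographic
patients.  Every planted patient carries a truth label naming the detection
stage that should admit or exclude it, which is what makes the downstream
pipeline testable without any real data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .adjudication import Classification, ReviewLabel
from .ehr_model import (
    CVX,
    ICD10CM,
    LOINC,
    CareSetting,
    Coding,
    ConditionRecord,
    DiagnosisRole,
    EhrBundle,
    EncounterRecord,
    Ethnicity,
    ImmunizationRecord,
    ObservationRecord,
    PatientRecord,
    Race,
    Sex,
    normalize_name,
)
from .errors import ConfigError

STUDY_START = date(2020, 12, 14)
STUDY_END = date(2023, 4, 28)
OBSERVATION_START = date(2019, 12, 14)


class PlantedCategory(str, Enum):
    true_in_window = "true_in_window"
    out_of_window = "out_of_window"
    prevalent = "prevalent"
    outpatient_only = "outpatient_only"
    unvaccinated = "unvaccinated"
    duplicate_demographics = "duplicate_demographics"
    background = "background"


@dataclass(frozen=True)
class TruthLabel:
    patient_id: str
    is_true_ae: bool
    planted_category: PlantedCategory
    evidence_complete: bool = True


def default_marginals() -> dict[str, dict[str, float]]:
    """Demographic marginals of a large academic health system population."""
    return {
        "age": {"<5": 0.0436, "5-17": 0.0558, "18-24": 0.0661,
                "25-44": 0.3097, "45-64": 0.2808, ">65": 0.2420},
        "sex": {"male": 0.4572, "female": 0.5406, "other": 0.0022},
        "race": {"white": 0.6058, "black": 0.1050, "asian_pacific": 0.0900,
                 "american_indian_alaska_native": 0.0030, "other": 0.0833,
                 "unknown": 0.1053, "declined": 0.0076},
        "ethnicity": {"hispanic": 0.1433, "non_hispanic": 0.7313, "unknown": 0.1254},
    }


_AGE_BOUNDS = {"<5": (0, 4), "5-17": (5, 17), "18-24": (18, 24),
               "25-44": (25, 44), "45-64": (45, 64), ">65": (65, 90)}

_FIRST_NAMES = [
    "James", "Mary", "Robert", "Patricia", "John", "Jennifer", "Michael", "Linda",
    "David", "Elizabeth", "William", "Barbara", "Richard", "Susan", "Joseph",
    "Jessica", "Thomas", "Sarah", "Charles", "Karen", "Christopher", "Lisa",
    "Daniel", "Nancy", "Matthew", "Betty", "Anthony", "Margaret", "Mark",
    "Sandra", "Donald", "Ashley", "Steven", "Kimberly", "Andrew", "Emily",
    "Paul", "Donna", "Joshua", "Michelle", "Kenneth", "Carol", "Kevin",
    "Amanda", "Brian", "Dorothy", "George", "Melissa",
]
_LAST_NAMES = [
    "Smith", "Johnson", "Williams", "Brown", "Jones", "Garcia", "Miller",
    "Davis", "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez",
    "Wilson", "Anderson", "Thomas", "Taylor", "Moore", "Jackson", "Martin",
    "Lee", "Perez", "Thompson", "White", "Harris", "Sanchez", "Clark",
    "Ramirez", "Lewis", "Robinson", "Walker", "Young", "Allen", "King",
    "Wright", "Scott", "Torres", "Nguyen", "Hill", "Flores", "Green",
    "Adams", "Nelson", "Baker", "Hall", "Rivera", "Campbell", "Mitchell",
]

# Concrete diagnosis codes drawn from the myocarditis/pericarditis family.
_TARGET_CODES = ["I40.0", "I40.1", "I40.8", "I40.9", "I41", "I51.4",
                 "I30.0", "I30.1", "I30.9", "I31.9", "I32"]
_EVIDENCE_CODES = ["6598-7", "10839-9", "42757-5", "49563-0", "30934-4"]
_VACCINE_CODES = ["207", "208", "211", "212", "213"]
_BACKGROUND_DX = ["J06.9", "E11.9", "I10", "K21.9", "M54.5", "F41.9", "N39.0", "J45.909"]
_BACKGROUND_OBS = ["2345-7", "718-7", "2093-3"]


@dataclass
class CohortSpec:
    """Parameters controlling one synthetic cohort.

    Planted-case counts name the structural category of the records created
    for those patients; ``truth_ppv`` controls what fraction of the cases the
    algorithm will flag carry a positive latent clinical label, and
    ``insufficient_evidence_rate`` what fraction of flagged cases have their
    confirmatory documentation withheld after the detection-relevant copies
    are planted.
    """

    n_patients: int = 200
    study_start: date = STUDY_START
    study_end: date = STUDY_END
    observation_start: date = OBSERVATION_START
    demographic_marginals: dict = field(default_factory=default_marginals)
    vaccination_coverage: float = 0.6
    n_true_cases: int = 0
    n_out_of_window_cases: int = 0
    n_prevalent_cases: int = 0
    n_outpatient_cases: int = 0
    n_unvaccinated_cases: int = 0
    n_duplicate_demographic_cases: int = 0
    insufficient_evidence_rate: float = 0.0
    truth_ppv: float = 1.0
    seed: int = 0

    def planted_total(self) -> int:
        # duplicate cases consume two patients each: the case and its clone
        return (self.n_true_cases + self.n_out_of_window_cases
                + self.n_prevalent_cases + self.n_outpatient_cases
                + self.n_unvaccinated_cases
                + 2 * self.n_duplicate_demographic_cases)

    def validate(self) -> None:
        for name in ("vaccination_coverage", "insufficient_evidence_rate", "truth_ppv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        counts = (self.n_patients, self.n_true_cases, self.n_out_of_window_cases,
                  self.n_prevalent_cases, self.n_outpatient_cases,
                  self.n_unvaccinated_cases, self.n_duplicate_demographic_cases)
        if any(c < 0 for c in counts):
            raise ConfigError("counts must be non-negative")
        if self.planted_total() > self.n_patients:
            raise ConfigError(
                f"planted cases ({self.planted_total()}, counting duplicate clones) "
                f"exceed n_patients ({self.n_patients})")
        if self.study_start < self.observation_start:
            raise ConfigError("study_start before observation_start")


class _Ids:
    def __init__(self) -> None:
        self.counters: dict[str, int] = {}

    def next(self, prefix: str) -> str:
        self.counters[prefix] = self.counters.get(prefix, 0) + 1
        return f"{prefix}{self.counters[prefix]:06d}"


class _Builder:
    """Mutable state threaded through one generate() call."""

    def __init__(self, spec: CohortSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.rng = rng
        self.ids = _Ids()
        self.bundle = EhrBundle()
        self.used_keys: set[tuple[str, str]] = set()
        self.practitioner_ids: list[str] = []

    # -- helpers -----------------------------------------------------------

    def _choice(self, margin: dict[str, float]) -> str:
        keys = list(margin)
        probs = np.array([margin[k] for k in keys], dtype=float)
        probs = probs / probs.sum()
        return keys[self.rng.choice(len(keys), p=probs)]

    def _day(self, lo: date, hi: date) -> date:
        span = (hi - lo).days
        return lo + timedelta(days=int(self.rng.integers(0, span + 1)))

    def make_patient(self, adult: bool = False,
                     clone_of: Optional[PatientRecord] = None) -> PatientRecord:
        m = self.spec.demographic_marginals
        pid = self.ids.next("P")
        if clone_of is not None:
            patient = PatientRecord(
                patient_id=pid, birth_date=clone_of.birth_date, sex=clone_of.sex,
                race=Race(self._choice(m["race"])),
                ethnicity=Ethnicity(self._choice(m["ethnicity"])),
                name_key=clone_of.name_key)
            self.bundle.patients.append(patient)
            return patient
        if adult:
            age_years = int(self.rng.integers(18, 81))
        else:
            lo, hi = _AGE_BOUNDS[self._choice(m["age"])]
            age_years = int(self.rng.integers(lo, hi + 1))
        birth = self.spec.study_start - timedelta(days=age_years * 365 + int(self.rng.integers(0, 365)))
        sex = Sex(self._choice(m["sex"]))
        for _ in range(1000):
            name = (f"{_FIRST_NAMES[self.rng.integers(0, len(_FIRST_NAMES))]} "
                    f"{_LAST_NAMES[self.rng.integers(0, len(_LAST_NAMES))]}")
            key = (normalize_name(name), birth.isoformat())
            if key not in self.used_keys:
                self.used_keys.add(key)
                break
        patient = PatientRecord(
            patient_id=pid, birth_date=birth, sex=sex,
            race=Race(self._choice(m["race"])),
            ethnicity=Ethnicity(self._choice(m["ethnicity"])),
            name_key=normalize_name(name))
        self.bundle.patients.append(patient)
        return patient

    def add_encounter(self, pid: str, setting: CareSetting, start: date,
                      duration: int = 0) -> EncounterRecord:
        enc = EncounterRecord(
            encounter_id=self.ids.next("E"), patient_id=pid, care_setting=setting,
            start_date=start, end_date=start + timedelta(days=duration))
        self.bundle.encounters.append(enc)
        return enc

    def add_condition(self, pid: str, code: str, onset: date,
                      role: DiagnosisRole = DiagnosisRole.final,
                      encounter_id: Optional[str] = None,
                      system: str = ICD10CM) -> ConditionRecord:
        cond = ConditionRecord(
            condition_id=self.ids.next("C"), patient_id=pid,
            code=Coding(system, code), onset_date=onset,
            diagnosis_role=role, encounter_id=encounter_id)
        self.bundle.conditions.append(cond)
        return cond

    def add_immunization(self, pid: str, day: date, code: Optional[str] = None) -> ImmunizationRecord:
        code = code or _VACCINE_CODES[self.rng.integers(0, len(_VACCINE_CODES))]
        imm = ImmunizationRecord(
            immunization_id=self.ids.next("I"), patient_id=pid,
            code=Coding(CVX, code), administration_date=day)
        self.bundle.immunizations.append(imm)
        return imm

    def add_observation(self, pid: str, code: str, day: date,
                        value: Optional[float] = None) -> ObservationRecord:
        obs = ObservationRecord(
            observation_id=self.ids.next("O"), patient_id=pid,
            code=Coding(LOINC, code), effective_date=day, value=value)
        self.bundle.observations.append(obs)
        return obs

    def add_passthrough(self, rtype: str, obj: dict) -> None:
        import json
        self.bundle.passthrough.setdefault(rtype, []).append(
            json.dumps(obj, sort_keys=True, separators=(",", ":")))

    # -- case structures ----------------------------------------------------

    def vaccinated_index(self, pid: str, offset_lo: int, offset_hi: int) -> date:
        """Plant a vaccination and return the diagnosis index date v + U."""
        u = int(self.rng.integers(offset_lo, offset_hi + 1))
        last_v = self.spec.study_end - timedelta(days=u)
        v = self._day(self.spec.study_start, last_v)
        if self.rng.random() < 0.5 and v - timedelta(days=28) >= self.spec.study_start:
            self.add_immunization(pid, v - timedelta(days=28))
        self.add_immunization(pid, v)
        return v + timedelta(days=u)

    def inpatient_target_event(self, pid: str, d: date, evidence: bool = True) -> None:
        enc = self.add_encounter(pid, CareSetting.inpatient, d,
                                 duration=int(self.rng.integers(1, 8)))
        code = _TARGET_CODES[self.rng.integers(0, len(_TARGET_CODES))]
        self.add_condition(pid, code, d, DiagnosisRole.final, enc.encounter_id)
        if self.rng.random() < 0.4:
            self.add_condition(pid, code, d, DiagnosisRole.admitting, enc.encounter_id)
        if evidence:
            obs_day = d + timedelta(days=int(self.rng.integers(-2, 3)))
            self.add_observation(pid, _EVIDENCE_CODES[self.rng.integers(0, len(_EVIDENCE_CODES))],
                                 obs_day, value=float(np.round(self.rng.uniform(0.1, 5.0), 2)))

    def reviewer_artifacts(self, pid: str, d: date, withhold: bool) -> None:
        """DiagnosticReport/DocumentReference pass-throughs shipped to reviewers.

        When ``withhold`` is set the confirmatory DiagnosticReport is omitted,
        so the case is still flagged by the algorithm (the detection copy of
        the evidence remains) but cannot be confirmed during review.
        """
        day = min(max(d, self.spec.study_start), self.spec.study_end).isoformat()
        if not withhold:
            pr = self.practitioner_ids[self.rng.integers(0, len(self.practitioner_ids))]
            self.add_passthrough("DiagnosticReport", {
                "resourceType": "DiagnosticReport", "id": self.ids.next("DR"),
                "subject": {"reference": f"Patient/{pid}"},
                "effectiveDateTime": day, "status": "final",
                "code": {"coding": [{"system": LOINC, "code": "11524-6"}]},
                "performer": [{"reference": f"Practitioner/{pr}"}]})
        self.add_passthrough("DocumentReference", {
            "resourceType": "DocumentReference", "id": self.ids.next("DOC"),
            "subject": {"reference": f"Patient/{pid}"},
            "date": day, "status": "current",
            "description": "synthetic clinical note stub"})

    def background_activity(self, patient: PatientRecord, vaccinate: bool) -> None:
        lo = max(self.spec.observation_start, patient.birth_date)
        for _ in range(int(self.rng.integers(0, 4))):
            start = self._day(lo, self.spec.study_end)
            setting = [CareSetting.outpatient, CareSetting.inpatient,
                       CareSetting.emergency][self.rng.choice(3, p=[0.8, 0.15, 0.05])]
            dur = 0 if setting == CareSetting.outpatient else int(self.rng.integers(1, 6))
            enc = self.add_encounter(patient.patient_id, setting, start, dur)
            if self.rng.random() < 0.6:
                self.add_condition(patient.patient_id,
                                   _BACKGROUND_DX[self.rng.integers(0, len(_BACKGROUND_DX))],
                                   start, DiagnosisRole.final, enc.encounter_id)
            if self.rng.random() < 0.3:
                self.add_observation(patient.patient_id,
                                     _BACKGROUND_OBS[self.rng.integers(0, len(_BACKGROUND_OBS))],
                                     start, value=float(np.round(self.rng.uniform(3, 200), 1)))
        if vaccinate and self.rng.random() < self.spec.vaccination_coverage:
            v1 = self._day(self.spec.study_start, self.spec.study_end)
            self.add_immunization(patient.patient_id, v1)
            v2 = v1 + timedelta(days=28)
            if self.rng.random() < 0.8 and v2 <= self.spec.study_end:
                self.add_immunization(patient.patient_id, v2)


def generate(spec: CohortSpec) -> tuple[EhrBundle, list[TruthLabel]]:
    """Generate a synthetic cohort with the requested planted case structure.

    Returns the bundle and one truth label per patient.  Identical spec and
    seed give byte-identical output when written with ``write_bundle``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    b = _Builder(spec, rng)

    for _ in range(3):
        b.practitioner_ids.append(b.ids.next("PR"))
    for pr in b.practitioner_ids:
        b.add_passthrough("Practitioner", {
            "resourceType": "Practitioner", "id": pr,
            "name": [{"text": "synthetic reviewer-facing practitioner"}]})
    for loc in range(2):
        b.add_passthrough("Location", {
            "resourceType": "Location", "id": b.ids.next("L"),
            "name": f"synthetic ward {loc}"})

    flagged_structure: list[str] = []  # true_in_window + duplicate cases, in creation order
    categories: list[tuple[PatientRecord, PlantedCategory]] = []
    dup_sources: list[PatientRecord] = []

    plan = ([PlantedCategory.true_in_window] * spec.n_true_cases
            + [PlantedCategory.out_of_window] * spec.n_out_of_window_cases
            + [PlantedCategory.prevalent] * spec.n_prevalent_cases
            + [PlantedCategory.outpatient_only] * spec.n_outpatient_cases
            + [PlantedCategory.unvaccinated] * spec.n_unvaccinated_cases
            + [PlantedCategory.duplicate_demographics] * spec.n_duplicate_demographic_cases)

    for category in plan:
        patient = b.make_patient(adult=True)
        pid = patient.patient_id
        categories.append((patient, category))
        if category in (PlantedCategory.true_in_window, PlantedCategory.duplicate_demographics):
            d = b.vaccinated_index(pid, 0, 42)
            b.inpatient_target_event(pid, d)
            flagged_structure.append(pid)
            if category == PlantedCategory.duplicate_demographics:
                dup_sources.append(patient)
        elif category == PlantedCategory.out_of_window:
            d = b.vaccinated_index(pid, 43, 120)
            b.inpatient_target_event(pid, d)
        elif category == PlantedCategory.prevalent:
            d = b.vaccinated_index(pid, 0, 42)
            b.inpatient_target_event(pid, d)
            prior = d - timedelta(days=int(rng.integers(30, 365)))
            b.add_condition(pid, _TARGET_CODES[rng.integers(0, len(_TARGET_CODES))], prior)
        elif category == PlantedCategory.outpatient_only:
            d = b.vaccinated_index(pid, 0, 42)
            enc = b.add_encounter(pid, CareSetting.outpatient, d)
            b.add_condition(pid, _TARGET_CODES[rng.integers(0, len(_TARGET_CODES))],
                            d, DiagnosisRole.final, enc.encounter_id)
            b.add_observation(pid, _EVIDENCE_CODES[rng.integers(0, len(_EVIDENCE_CODES))],
                              d, value=float(np.round(rng.uniform(0.1, 5.0), 2)))
        elif category == PlantedCategory.unvaccinated:
            d = b._day(spec.study_start, spec.study_end)
            b.inpatient_target_event(pid, d)
        b.background_activity(patient, vaccinate=False)

    n_background = spec.n_patients - len(plan) - len(dup_sources)
    for _ in range(n_background):
        patient = b.make_patient()
        categories.append((patient, PlantedCategory.background))
        b.background_activity(patient, vaccinate=True)
    for source in dup_sources:
        patient = b.make_patient(clone_of=source)
        categories.append((patient, PlantedCategory.background))
        b.background_activity(patient, vaccinate=True)

    # Withhold reviewer documentation for a quota of the retrievable flagged
    # cases (the true_in_window patients; duplicate-demographic cases are never
    # retrieved, so withholding there would be invisible).
    retrievable = [p.patient_id for p, c in categories
                   if c == PlantedCategory.true_in_window]
    n_withheld = int(round(spec.insufficient_evidence_rate * len(retrievable)))
    withheld = set(np.array(retrievable)[rng.permutation(len(retrievable))[:n_withheld]].tolist()) \
        if retrievable else set()

    # Latent truth: an exact quota of the adjudicable cases (retrievable with
    # complete evidence) is positive, so a cohort's realized flagged-case PPV
    # equals round(truth_ppv * n) / n rather than a binomial draw around it.
    adjudicable = [pid for pid in retrievable if pid not in withheld]
    adjudicable_set = set(adjudicable)
    n_pos = int(round(spec.truth_ppv * len(adjudicable)))
    positive = set(np.array(adjudicable)[rng.permutation(len(adjudicable))[:n_pos]].tolist()) \
        if adjudicable else set()

    labels: list[TruthLabel] = []
    index_dates: dict[str, date] = {}
    for cond in b.bundle.conditions:
        if cond.encounter_id is not None and cond.code.code in _TARGET_CODES:
            prev = index_dates.get(cond.patient_id)
            if prev is None or cond.onset_date < prev:
                index_dates[cond.patient_id] = cond.onset_date
    for patient, category in categories:
        pid = patient.patient_id
        evidence_complete = pid not in withheld
        if category in (PlantedCategory.true_in_window, PlantedCategory.duplicate_demographics):
            if pid in positive:
                is_true = True
            elif pid in adjudicable_set:
                is_true = False
            else:  # withheld-evidence or duplicate cases: latent truth is moot downstream
                is_true = bool(rng.random() < spec.truth_ppv)
            b.reviewer_artifacts(pid, index_dates.get(pid, spec.study_start),
                                 withhold=not evidence_complete)
        else:
            is_true = False
        labels.append(TruthLabel(patient_id=pid, is_true_ae=is_true,
                                 planted_category=category,
                                 evidence_complete=evidence_complete))
    return b.bundle, labels


# ---------------------------------------------------------------------------
# Truth-label I/O
# ---------------------------------------------------------------------------

def write_truth_labels(labels: list[TruthLabel], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "is_true_ae", "planted_category", "evidence_complete"])
        for lab in labels:
            w.writerow([lab.patient_id, int(lab.is_true_ae),
                        lab.planted_category.value, int(lab.evidence_complete)])


def read_truth_labels(path: Union[str, Path]) -> list[TruthLabel]:
    with Path(path).open() as fh:
        return [
            TruthLabel(patient_id=row["patient_id"],
                       is_true_ae=bool(int(row["is_true_ae"])),
                       planted_category=PlantedCategory(row["planted_category"]),
                       evidence_complete=bool(int(row["evidence_complete"])))
            for row in csv.DictReader(fh)
        ]


# ---------------------------------------------------------------------------
# Deterministic attrition-flow fixture
# ---------------------------------------------------------------------------

@dataclass
class ConsortFixture:
    """A shipped deterministic scenario exercising the whole pipeline.

    Thirty cases are flagged by detection; four share demographics with a
    second patient and are dropped by the multi-match privacy exclusion;
    two of the twenty-six retrieved lack confirmatory documentation; the
    remaining twenty-four are adjudicated as 3 definite, 11 probable,
    0 possible and 10 doubtful, so the primary PPV is 14/24.
    """

    bundle: EhrBundle
    truth_labels: list[TruthLabel]
    reviews: list[tuple[ReviewLabel, ReviewLabel]]
    spec: CohortSpec


def consort_scenario() -> ConsortFixture:
    spec = CohortSpec(
        n_patients=64,
        n_true_cases=26,
        n_duplicate_demographic_cases=4,
        insufficient_evidence_rate=2 / 26,
        truth_ppv=14 / 24,
        vaccination_coverage=0.65,
        seed=20201214,
    )
    bundle, labels = generate(spec)
    by_id = {lab.patient_id: lab for lab in labels}
    retrievable = sorted(lab.patient_id for lab in labels
                         if lab.planted_category == PlantedCategory.true_in_window)
    positives = [pid for pid in retrievable
                 if by_id[pid].evidence_complete and by_id[pid].is_true_ae]
    reviews: list[tuple[ReviewLabel, ReviewLabel]] = []
    for pid in retrievable:
        lab = by_id[pid]
        if not lab.evidence_complete:
            cls = Classification.insufficient_evidence
        elif lab.is_true_ae:
            cls = Classification.definite if positives.index(pid) < 3 else Classification.probable
        else:
            cls = Classification.doubtful
        reviews.append((ReviewLabel(case_id=pid, reviewer_id="R1", classification=cls),
                        ReviewLabel(case_id=pid, reviewer_id="R2", classification=cls)))
    return ConsortFixture(bundle=bundle, truth_labels=labels, reviews=reviews, spec=spec)


def spec_to_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    for k in ("study_start", "study_end", "observation_start"):
        d[k] = d[k].isoformat()
    return d
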