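"""The computable-phenotype detection algorithm with attrition accounting.

Detection walks ordered filter stages from raw encounters to flagged case
candidates: encounters inside the study period, the allowed care settings
(inpatient by default), a target-diagnosis code match that ignores
admitting-only diagnoses, a supporting-evidence requirement near the index
date, a clean window establishing that the diagnosis is incident rather than
prevalent, and finally the vaccine exposure requirement that the diagnosis
fall 0-42 days after a qualifying immunization.  Every stage's entering and
surviving counts are recorded in a CONSORT-style attrition report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

from .ehr_model import (
    CareSetting,
    Coding,
    ConditionRecord,
    ConceptRole,
    DiagnosisRole,
    EhrBundle,
    EncounterRecord,
    ImmunizationRecord,
    ValueSet,
    valuesets_by_role,
)
from .errors import ConfigError

# The conjunctive per-case stages (order is reportable, not semantic).
CASE_STAGES = ("target_diagnosis", "supporting_evidence", "clean_window", "vaccine_exposure")


@dataclass(frozen=True)
class RiskWindow:
    """Closed integer day interval relative to vaccination; day 0 included."""

    lower: int = 0
    upper: int = 42

    def __post_init__(self) -> None:
        if self.lower < 0 or self.upper < self.lower:
            raise ConfigError(f"invalid risk window [{self.lower}, {self.upper}]")


@dataclass
class PhenotypeConfig:
    study_start: date = date(2020, 12, 14)
    study_end: date = date(2023, 4, 28)
    observation_start: date = date(2019, 12, 14)
    risk_window: RiskWindow = field(default_factory=RiskWindow)
    clean_window_days: int = 365
    care_settings: frozenset[CareSetting] = frozenset({CareSetting.inpatient})
    require_supporting_evidence: bool = True
    supporting_evidence_window_days: int = 7
    exclude_admitting_only: bool = True
    one_case_per_patient: bool = True

    def validate(self) -> None:
        if self.clean_window_days < 1:
            raise ConfigError("clean_window_days must be >= 1")
        if (self.study_start - self.observation_start).days < self.clean_window_days:
            raise ConfigError(
                "study_start must allow a full clean window of observation: "
                f"{self.study_start} < {self.observation_start} + {self.clean_window_days}d")
        if not self.care_settings:
            raise ConfigError("care_settings must not be empty")


@dataclass(frozen=True)
class CaseCandidate:
    patient_id: str
    index_diagnosis_date: date
    index_encounter_id: str
    matched_diagnosis_codes: tuple[str, ...]
    qualifying_immunization_id: str
    exposure_offset_days: int
    supporting_evidence_ids: tuple[str, ...]
    demographics: dict


@dataclass(frozen=True)
class AttritionStage:
    stage_name: str
    entering_count: int
    surviving_count: int
    unit: str  # encounters | cases | patients
    detail: dict = field(default_factory=dict, hash=False, compare=False)


@dataclass
class AttritionReport:
    stages: list[AttritionStage] = field(default_factory=list)

    def add(self, name: str, entering: int, surviving: int, unit: str, **detail) -> None:
        if surviving > entering:
            raise ValueError(f"stage {name}: surviving {surviving} > entering {entering}")
        self.stages.append(AttritionStage(name, entering, surviving, unit, dict(detail)))

    def validate(self) -> None:
        prev: Optional[AttritionStage] = None
        for stage in self.stages:
            assert stage.surviving_count <= stage.entering_count
            if prev is not None and prev.unit == stage.unit:
                assert stage.entering_count == prev.surviving_count, (
                    f"stage {stage.stage_name} entering != previous surviving")
            prev = stage

    def to_dict(self) -> dict:
        return {"stages": [
            {"stage": s.stage_name, "entering": s.entering_count,
             "surviving": s.surviving_count, "unit": s.unit, **s.detail}
            for s in self.stages]}


# ---------------------------------------------------------------------------
# Stage primitives
# ---------------------------------------------------------------------------

def in_risk_window(vaccination_date: date, diagnosis_date: date,
                   window: RiskWindow = RiskWindow()) -> Optional[int]:
    """Whole-day offset of diagnosis after vaccination, if inside the window.

    Same-day diagnosis (offset 0) qualifies; a diagnosis before vaccination
    or beyond the upper bound returns None.
    """
    offset = (diagnosis_date - vaccination_date).days
    if window.lower <= offset <= window.upper:
        return offset
    return None


def select_exposure(
    immunizations: Iterable[ImmunizationRecord],
    diagnosis_date: date,
    vaccine_valuesets: Sequence[ValueSet],
    window: RiskWindow = RiskWindow(),
) -> Optional[tuple[ImmunizationRecord, int]]:
    """The qualifying dose: smallest in-window offset, i.e. the latest dose
    at or before diagnosis.  Ties on offset break on immunization id so the
    choice is deterministic."""
    best: Optional[tuple[ImmunizationRecord, int]] = None
    for imm in immunizations:
        if not any(vs.contains(imm.code) for vs in vaccine_valuesets):
            continue
        offset = in_risk_window(imm.administration_date, diagnosis_date, window)
        if offset is None:
            continue
        if best is None or (offset, imm.immunization_id) < (best[1], best[0].immunization_id):
            best = (imm, offset)
    return best


def passes_clean_window(
    conditions: Iterable[ConditionRecord],
    patient_id: str,
    index_date: date,
    target_valuesets: Sequence[ValueSet],
    lookback_days: int = 365,
    observation_start: Optional[date] = None,
) -> bool:
    """True iff no target-coded condition falls in [index - lookback, index).

    The interval is half-open so same-day repeat codes of the incident
    diagnosis do not disqualify it.  If the patient's lookback would begin
    before the observation period, the case is indeterminate and fails
    (conservative: insufficient history is not assumed clean).
    """
    window_start = index_date - timedelta(days=lookback_days)
    if observation_start is not None and window_start < observation_start:
        return False
    for cond in conditions:
        if cond.patient_id != patient_id:
            continue
        if not window_start <= cond.onset_date < index_date:
            continue
        if any(vs.contains(cond.code) for vs in target_valuesets):
            return False
    return True


# ---------------------------------------------------------------------------
# Full detection
# ---------------------------------------------------------------------------

def detect(
    bundle: EhrBundle,
    valuesets: Sequence[ValueSet],
    config: PhenotypeConfig,
    stage_order: Optional[Sequence[str]] = None,
) -> tuple[list[CaseCandidate], AttritionReport]:
    """Run the phenotype over a bundle and report per-stage attrition.

    ``stage_order`` permutes the four conjunctive case-level predicates
    (default ``CASE_STAGES``); the final candidate set is invariant to the
    permutation, only the attrition counts move between stages.
    """
    config.validate()
    by_role = valuesets_by_role(valuesets)
    target_vs = by_role.get(ConceptRole.target_diagnosis, [])
    vaccine_vs = by_role.get(ConceptRole.exposure_vaccine, [])
    evidence_vs = by_role.get(ConceptRole.supporting_evidence, [])
    if not target_vs:
        raise ConfigError("no target_diagnosis value set provided")
    if not vaccine_vs:
        raise ConfigError("no exposure_vaccine value set provided")
    if config.require_supporting_evidence and not evidence_vs:
        raise ConfigError("supporting evidence required but no supporting_evidence value set")
    order = tuple(stage_order) if stage_order is not None else CASE_STAGES
    if sorted(order) != sorted(CASE_STAGES):
        raise ConfigError(f"stage_order must be a permutation of {CASE_STAGES}")

    report = AttritionReport()

    # Stage 1: encounters overlapping the study period.
    n_enc = len(bundle.encounters)
    in_period = [e for e in bundle.encounters
                 if e.start_date <= config.study_end and e.end_date >= config.study_start]
    report.add("study_period_encounters", n_enc, len(in_period), "encounters")

    # Stage 2: allowed care settings.
    qualifying = [e for e in in_period if e.care_setting in config.care_settings]
    report.add("care_setting", len(in_period), len(qualifying), "encounters",
               settings=sorted(s.value for s in config.care_settings))
    qualifying_by_id = {e.encounter_id: e for e in qualifying}

    # Candidate events: conditions attached to a qualifying encounter.
    events = [c for c in bundle.conditions
              if c.encounter_id is not None and c.encounter_id in qualifying_by_id]

    imms_by_patient: dict[str, list[ImmunizationRecord]] = {}
    for imm in bundle.immunizations:
        imms_by_patient.setdefault(imm.patient_id, []).append(imm)
    conds_by_patient: dict[str, list[ConditionRecord]] = {}
    for cond in bundle.conditions:
        conds_by_patient.setdefault(cond.patient_id, []).append(cond)
    obs_by_patient: dict[str, list] = {}
    for obs in bundle.observations:
        obs_by_patient.setdefault(obs.patient_id, []).append(obs)

    def evidence_ids(cond: ConditionRecord) -> tuple[str, ...]:
        w = timedelta(days=config.supporting_evidence_window_days)
        return tuple(sorted(
            o.observation_id for o in obs_by_patient.get(cond.patient_id, [])
            if any(vs.contains(o.code) for vs in evidence_vs)
            and cond.onset_date - w <= o.effective_date <= cond.onset_date + w))

    def p_target(cond: ConditionRecord) -> bool:
        if config.exclude_admitting_only and cond.diagnosis_role == DiagnosisRole.admitting:
            return False
        if not (config.study_start <= cond.onset_date <= config.study_end):
            return False
        return any(vs.contains(cond.code) for vs in target_vs)

    def p_evidence(cond: ConditionRecord) -> bool:
        if not config.require_supporting_evidence:
            return True
        return bool(evidence_ids(cond))

    def p_clean(cond: ConditionRecord) -> bool:
        return passes_clean_window(
            conds_by_patient.get(cond.patient_id, []), cond.patient_id,
            cond.onset_date, target_vs, config.clean_window_days,
            config.observation_start)

    def p_exposure(cond: ConditionRecord) -> bool:
        return select_exposure(imms_by_patient.get(cond.patient_id, []),
                               cond.onset_date, vaccine_vs, config.risk_window) is not None

    predicates = {"target_diagnosis": p_target, "supporting_evidence": p_evidence,
                  "clean_window": p_clean, "vaccine_exposure": p_exposure}

    surviving = events
    for stage in order:
        entering = surviving
        surviving = [c for c in entering if predicates[stage](c)]
        report.add(stage, len(entering), len(surviving), "cases",
                   surviving_patients=len({c.patient_id for c in surviving}))

    # Stage 7: one case per patient (earliest index date, then smallest id).
    entering = surviving
    if config.one_case_per_patient:
        best: dict[str, ConditionRecord] = {}
        for cond in entering:
            cur = best.get(cond.patient_id)
            if cur is None or (cond.onset_date, cond.condition_id) < (cur.onset_date, cur.condition_id):
                best[cond.patient_id] = cond
        surviving = sorted(best.values(), key=lambda c: c.condition_id)
    report.add("one_case_per_patient", len(entering), len(surviving), "cases",
               surviving_patients=len({c.patient_id for c in surviving}))

    patients_by_id = {p.patient_id: p for p in bundle.patients}
    candidates: list[CaseCandidate] = []
    for cond in surviving:
        exposure = select_exposure(imms_by_patient.get(cond.patient_id, []),
                                   cond.onset_date, vaccine_vs, config.risk_window)
        assert exposure is not None
        imm, offset = exposure
        same_index_codes = tuple(sorted({
            c.code.code for c in events
            if c.patient_id == cond.patient_id and c.onset_date == cond.onset_date
            and any(vs.contains(c.code) for vs in target_vs)
            and not (config.exclude_admitting_only and c.diagnosis_role == DiagnosisRole.admitting)}))
        patient = patients_by_id[cond.patient_id]
        candidates.append(CaseCandidate(
            patient_id=cond.patient_id,
            index_diagnosis_date=cond.onset_date,
            index_encounter_id=cond.encounter_id,
            matched_diagnosis_codes=same_index_codes,
            qualifying_immunization_id=imm.immunization_id,
            exposure_offset_days=offset,
            supporting_evidence_ids=evidence_ids(cond),
            demographics={"name_key": patient.name_key,
                          "birth_date": patient.birth_date.isoformat(),
                          "sex": patient.sex.value},
        ))
    report.validate()
    return candidates, report
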