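from datetime import date, timedelta
from itertools import permutations

import pytest

from phenoval import (CohortSpec, PhenotypeConfig, PlantedCategory, RiskWindow,
                      generate, in_risk_window, passes_clean_window,
                      select_exposure, detect)
from phenoval.ehr_model import (CVX, ICD10CM, Coding, ConditionRecord,
                                ImmunizationRecord)
from phenoval.errors import ConfigError
from phenoval.phenotype_engine import CASE_STAGES

from _oracles import brute_force_candidates


def _imm(iid, day, code="207"):
    return ImmunizationRecord(iid, "P1", Coding(CVX, code), day)


def _cond(cid, day, code="I40.9"):
    return ConditionRecord(cid, "P1", Coding(ICD10CM, code), day)


class TestRiskWindow:
    @pytest.mark.parametrize("vax, dx, expected", [
        (date(2021, 3, 1), date(2021, 3, 1), 0),      # same-day dose counts
        (date(2021, 3, 1), date(2021, 4, 12), 42),    # upper boundary
        (date(2021, 3, 1), date(2021, 4, 13), None),  # one past the boundary
        (date(2021, 3, 1), date(2021, 2, 28), None),  # diagnosis before vaccination
    ])
    def test_boundaries(self, vax, dx, expected):
        assert in_risk_window(vax, dx) == expected

    def test_invalid_window_rejected(self):
        with pytest.raises(ConfigError):
            RiskWindow(lower=-1, upper=10)
        with pytest.raises(ConfigError):
            RiskWindow(lower=10, upper=5)


class TestSelectExposure:
    def test_latest_in_window_dose_wins(self, valuesets):
        dx = date(2021, 6, 1)
        doses = [_imm("I1", dx - timedelta(days=60)),
                 _imm("I2", dx - timedelta(days=10))]
        picked = select_exposure(doses, dx, valuesets)
        assert picked is not None and picked[0].immunization_id == "I2" and picked[1] == 10

    def test_out_of_window_only_dose_is_absent(self, valuesets):
        dx = date(2021, 6, 1)
        assert select_exposure([_imm("I1", dx - timedelta(days=50))], dx, valuesets) is None

    def test_non_vaccine_code_is_gated_by_valueset(self, valuesets):
        dx = date(2021, 6, 1)
        flu = _imm("I1", dx - timedelta(days=5), code="141")  # influenza CVX
        assert select_exposure([flu], dx, valuesets) is None

    def test_agrees_with_brute_force_over_many_dose_sets(self, valuesets):
        import numpy as np
        rng = np.random.default_rng(0)
        dx = date(2021, 6, 1)
        window = RiskWindow()
        for _ in range(200):
            doses = [_imm(f"I{k}", dx - timedelta(days=int(o)))
                     for k, o in enumerate(rng.integers(-30, 200, size=rng.integers(0, 6)))]
            picked = select_exposure(doses, dx, valuesets, window)
            offsets = [(dx - d.administration_date).days for d in doses]
            valid = [o for o in offsets if 0 <= o <= 42]
            if not valid:
                assert picked is None
            else:
                assert picked is not None and picked[1] == min(valid)


class TestCleanWindow:
    def test_prior_code_inside_lookback_disqualifies(self, valuesets):
        index = date(2021, 6, 1)
        prior = [_cond("C1", index - timedelta(days=100))]
        assert not passes_clean_window(prior, "P1", index, valuesets)

    def test_prior_code_outside_lookback_is_clean(self, valuesets):
        index = date(2021, 6, 1)
        prior = [_cond("C1", index - timedelta(days=400))]
        assert passes_clean_window(prior, "P1", index, valuesets)

    def test_no_priors_is_clean_and_same_day_does_not_disqualify(self, valuesets):
        index = date(2021, 6, 1)
        assert passes_clean_window([], "P1", index, valuesets)
        assert passes_clean_window([_cond("C1", index)], "P1", index, valuesets)

    def test_insufficient_observation_history_fails(self, valuesets):
        index = date(2020, 6, 1)  # < 365 days after observation start
        assert not passes_clean_window([], "P1", index, valuesets,
                                       observation_start=date(2019, 12, 14))


class TestDetect:
    def test_matches_brute_force_oracle(self, mixed_cohort, mixed_detect, valuesets):
        _, bundle, _ = mixed_cohort
        candidates, _ = mixed_detect
        expected = brute_force_candidates(bundle, valuesets, PhenotypeConfig())
        assert {(c.patient_id, c.index_diagnosis_date) for c in candidates} == expected

    def test_truth_labels_predict_candidate_membership(self, mixed_cohort, mixed_detect):
        _, _, labels = mixed_cohort
        flagged = {c.patient_id for c in mixed_detect[0]}
        should_flag = {PlantedCategory.true_in_window,
                       PlantedCategory.duplicate_demographics}
        for lab in labels:
            assert (lab.patient_id in flagged) == (lab.planted_category in should_flag), \
                (lab.patient_id, lab.planted_category)

    def test_zero_immunizations_lost_at_exposure_stage(self, valuesets):
        bundle, _ = generate(CohortSpec(n_patients=20, n_unvaccinated_cases=5, seed=4))
        bundle.immunizations = []
        candidates, report = detect(bundle, valuesets, PhenotypeConfig())
        assert candidates == []
        stage = {s.stage_name: s for s in report.stages}["vaccine_exposure"]
        assert stage.entering_count > 0 and stage.surviving_count == 0

    def test_attrition_is_monotone_and_chained(self, mixed_detect):
        _, report = mixed_detect
        report.validate()
        for s in report.stages:
            assert s.surviving_count <= s.entering_count

    def test_candidate_invariants(self, mixed_detect):
        candidates, _ = mixed_detect
        assert candidates
        for c in candidates:
            assert 0 <= c.exposure_offset_days <= 42
            assert c.supporting_evidence_ids
            assert c.matched_diagnosis_codes

    def test_stage_order_does_not_change_final_candidates(self, mixed_cohort, valuesets):
        """Stages 3-6 are conjunctive predicates: permuting them moves the
        attrition counts but never the final candidate set."""
        _, bundle, _ = mixed_cohort
        config = PhenotypeConfig()
        baseline = {(c.patient_id, c.index_diagnosis_date)
                    for c in detect(bundle, valuesets, config)[0]}
        for order in list(permutations(CASE_STAGES))[1:8:2]:
            permuted = {(c.patient_id, c.index_diagnosis_date)
                        for c in detect(bundle, valuesets, config, stage_order=order)[0]}
            assert permuted == baseline

    def test_widening_risk_window_never_removes_candidates(self, mixed_cohort, valuesets):
        _, bundle, _ = mixed_cohort
        narrow = detect(bundle, valuesets, PhenotypeConfig())[0]
        wide = detect(bundle, valuesets,
                      PhenotypeConfig(risk_window=RiskWindow(0, 130)))[0]
        assert {c.patient_id for c in narrow} <= {c.patient_id for c in wide}
        # the out-of-window plants (offsets 43-120) are picked up by the wide window
        assert len(wide) > len(narrow)

    def test_missing_required_valueset_is_fatal(self, mixed_cohort, valuesets):
        _, bundle, _ = mixed_cohort
        no_vaccine = [vs for vs in valuesets if vs.role.value != "exposure_vaccine"]
        with pytest.raises(ConfigError):
            detect(bundle, no_vaccine, PhenotypeConfig())

    def test_config_requires_full_clean_window_coverage(self):
        with pytest.raises(ConfigError):
            PhenotypeConfig(observation_start=date(2020, 6, 1)).validate()
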