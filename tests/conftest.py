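import pytest

from phenoval import (CohortSpec, PhenotypeConfig, consort_scenario,
                      default_valuesets, detect, generate, run_pipeline)

MIXED_SPEC = CohortSpec(
    n_patients=1000,
    n_true_cases=25,
    n_out_of_window_cases=20,
    n_prevalent_cases=20,
    n_outpatient_cases=20,
    n_unvaccinated_cases=20,
    n_duplicate_demographic_cases=10,
    insufficient_evidence_rate=0.1,
    truth_ppv=0.7,
    seed=42,
)


@pytest.fixture(scope="session")
def valuesets():
    return default_valuesets()


@pytest.fixture(scope="session")
def scenario():
    return consort_scenario()


@pytest.fixture(scope="session")
def scenario_result(scenario):
    return run_pipeline(scenario.bundle, scenario.truth_labels,
                        prescribed_reviews=scenario.reviews)


@pytest.fixture(scope="session")
def mixed_cohort():
    """A 1,000-patient cohort spanning every planted case category."""
    bundle, labels = generate(MIXED_SPEC)
    return MIXED_SPEC, bundle, labels


@pytest.fixture(scope="session")
def mixed_detect(mixed_cohort, valuesets):
    _, bundle, _ = mixed_cohort
    return detect(bundle, valuesets, PhenotypeConfig())
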