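import pytest
from hypothesis import HealthCheck, settings

import dietrisk as dr

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FIXTURE_SEED = 20260929


@pytest.fixture(scope="session")
def consumption():
    return dr.default_consumption()


@pytest.fixture(scope="session")
def demographics():
    return dr.default_demographics()


@pytest.fixture(scope="session")
def toxicity():
    return dr.default_toxicity()


@pytest.fixture(scope="session")
def study_datasets():
    return dr.build_study_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def goose_pcb(study_datasets):
    return next(
        d for d in study_datasets
        if d.food_id == "goose" and d.contaminant_id == "PCB 153"
    )


@pytest.fixture(scope="session")
def duck_pbb(study_datasets):
    return next(
        d for d in study_datasets
        if d.food_id == "duck" and d.contaminant_id == "PBB 153"
    )


@pytest.fixture(scope="session")
def run_outcome(study_datasets, consumption, demographics, toxicity):
    """One full pipeline run on the synthetic study, shared across tests."""
    cfg = dr.RunConfig(seed=FIXTURE_SEED, n_iter=10000)
    return dr.assess(study_datasets, consumption, demographics, toxicity, cfg)
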