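import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_dataset():
    """The deterministic seven-sire, 420-progeny reconstructed study dataset."""
    from sirehap import make_table1_fixture

    return make_table1_fixture()


@pytest.fixture(scope="session")
def study_analysis(study_dataset):
    """Full-pipeline run on the study dataset (classifications, results, pooled)."""
    from sirehap import analyze_dataset

    return analyze_dataset(study_dataset)
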