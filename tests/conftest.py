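import pytest

from retscreen.benchmark import build_benchmark_cohort
from retscreen.synthcohort import generate_cohort, paper_default_config


@pytest.fixture(scope="session")
def benchmark_cohort():
    return build_benchmark_cohort(seed=0)


@pytest.fixture(scope="session")
def default_config():
    return paper_default_config(seed=11)


@pytest.fixture(scope="session")
def synthetic_cohort(default_config):
    return generate_cohort(default_config)
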