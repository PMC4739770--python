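import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bench():
    """The default synthetic benchmark library (5 folds x 4 domains, 3
    planted fragments at 40% identity / 0.5 A noise, seed 1)."""
    from fragvocab.synthetic import generate_library

    records, truth = generate_library()
    return records, truth


@pytest.fixture(scope="session")
def bench_records(bench):
    return bench[0]


@pytest.fixture(scope="session")
def bench_truth(bench):
    return bench[1]


@pytest.fixture(scope="session")
def bench_by_id(bench_records):
    return {r.domain_id: r for r in bench_records}


@pytest.fixture(scope="session")
def bench_profiles(bench_records):
    from fragvocab.pipeline import build_profiles

    return build_profiles(bench_records)


@pytest.fixture(scope="session")
def bench_null(bench_profiles):
    from fragvocab.profiles import calibrate_null

    return calibrate_null(list(bench_profiles.values()), n_pairs=600, seed=11)


@pytest.fixture(scope="session")
def bench_result(bench_records):
    """Full detection run on the benchmark (shared across tests)."""
    from fragvocab.pipeline import run_detection

    return run_detection(bench_records)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
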