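import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny():
    from crthte.fixtures import tiny_dataset

    return tiny_dataset(seed=20230)


@pytest.fixture(scope="session")
def medium_dataset():
    """One moderately sized dataset (K=20, 50 staff) for estimation tests."""
    from crthte import ScenarioSpec, build_coefficients, simulate_dataset

    spec = ScenarioSpec.from_id(9)
    coefs = build_coefficients(spec)
    clusters, individuals, allocation, summaries = simulate_dataset(
        spec, 20, coefs, seed=77, n_staff=50, n_candidates=2000
    )
    return {
        "clusters": clusters,
        "individuals": individuals,
        "allocation": allocation,
        "summaries": summaries,
    }
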