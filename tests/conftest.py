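import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def analytic_dataset():
    """A mid-sized synthetic table with the deficit-response ground truth."""
    from acvoanfis.synthetic import SyntheticConfig, generate

    return generate(SyntheticConfig(n_rows=300, rng_seed=7, noise_sd=0.02))


@pytest.fixture(scope="session")
def small_template():
    from acvoanfis.training import AnfisTemplate

    return AnfisTemplate(n_inputs=3, n_rules=2)
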