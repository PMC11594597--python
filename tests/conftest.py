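import pytest

from bpround import GeneratorConfig, RoundingRule, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort, sized for fast unit tests."""
    return generate_cohort(GeneratorConfig(n_people=4000, seed=11))


@pytest.fixture()
def rule():
    return RoundingRule(rng_seed=3)
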