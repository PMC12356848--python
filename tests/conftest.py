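import pytest

from hgsoc_kinetics import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic cohort at the default study conditions (34 patients)."""
    return generate(GeneratorConfig(), seed=7)


@pytest.fixture(scope="session")
def big_cohort():
    """Larger synthetic cohort for estimation-accuracy checks."""
    return generate(GeneratorConfig(n_patients=120), seed=11)
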