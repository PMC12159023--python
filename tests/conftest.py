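import numpy as np
import pytest

from pikathresh import GeneratorConfig, build_plot_indicators, generate_survey


@pytest.fixture(scope="session")
def survey():
    """One default two-type survey (30 AM + 26 AS plots), fixed seed."""
    return generate_survey(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def indicators(survey):
    return build_plot_indicators(survey.quadrats, survey.plots)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
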