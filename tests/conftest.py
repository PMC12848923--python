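import numpy as np
import pytest

from hydroniche.isotopes import summarize_sources
from hydroniche.mixing import MixingConfig
from hydroniche.synthetic import (
    GeneratorSettings,
    default_chronosequence,
    generate_soil_profile,
)


@pytest.fixture(scope="session")
def settings():
    return GeneratorSettings(seed=20220715)


@pytest.fixture(scope="session")
def natural_site():
    """The natural-vegetation control site of the default chronosequence."""
    return default_chronosequence()[-1]


@pytest.fixture(scope="session")
def natural_sources(settings, natural_site):
    """Eight soil-layer source summaries from one generated profile."""
    soil = generate_soil_profile(natural_site, settings)
    return summarize_sources(soil)


@pytest.fixture()
def fast_mixing():
    """Short chain plan for unit tests (not for accuracy-sensitive checks)."""
    return MixingConfig(n_chains=2, iterations=4000, burn_in=2000, thin=4, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
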