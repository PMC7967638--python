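import math

import pytest

from prenatal_risk import load_published_counts
from prenatal_risk.pipeline import crude_fits_from_tables
from prenatal_risk.simulate import GeneratorConfig


@pytest.fixture(scope="session")
def published_counts():
    """Published per-category count tables, one per variable."""
    return load_published_counts()


@pytest.fixture(scope="session")
def published_crude_fits(published_counts):
    """Crude exact fits of every published count table (session-cached:
    these back several tests and take a few seconds to enumerate)."""
    return crude_fits_from_tables(published_counts)


@pytest.fixture(scope="session")
def small_generator_config():
    """One-factor synthetic design: cheap to generate and to fit exactly."""
    return GeneratorConfig(
        n=400,
        category_probs={"abortion_history": {"no": 0.8, "yes": 0.2}},
        municipality_patterns=((1.0, frozenset()),),
        true_log_odds={("abortion_history", "yes"): math.log(5.0)},
        target_prevalence=0.05,
        seed=11,
    )
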