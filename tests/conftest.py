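import numpy as np
import pytest

from endotyper import GeneratorConfig, generate_cohort
from endotyper.pipeline import discover_endotypes


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=3121) shared across the suite."""
    return generate_cohort(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def discovery(default_cohort):
    """Endotype discovery on the shared cohort (the expensive pipeline run)."""
    return discover_endotypes(default_cohort, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for cheap structural checks."""
    return generate_cohort(GeneratorConfig(seed=3, n_subjects=400))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
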