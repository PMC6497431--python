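import numpy as np
import pytest

from methrisk.synthetic_cohort import GeneratorConfig, generate_biopsy_series, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort (35 malignant / 23 benign) shared across
    read-only tests."""
    config = GeneratorConfig(seed=101)
    patients, samples = generate_cohort(config)
    biopsies = generate_biopsy_series(patients, config)
    return config, patients, samples + biopsies
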