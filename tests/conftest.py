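import numpy as np
import pytest

from fwctex.synthetic import CohortConfig, generate_cohort
from fwctex.stats import run_full_analysis


@pytest.fixture(scope="session")
def default_cohort():
    """A 30-patient cohort at the default calibration, fixed seed."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Full pipeline result on the default cohort (shared; ~15 s once)."""
    return run_full_analysis(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
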