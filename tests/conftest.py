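import pytest

from methylprofiler import SimulationConfig, simulate_cohort
from methylprofiler.fraction_model import fraction_matrix
from methylprofiler.io_formats import pivot_fractions


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (recorded seed 42), shared across tests."""
    return simulate_cohort(SimulationConfig(), seed=42)


@pytest.fixture(scope="session")
def default_fractions(default_cohort):
    """Measured hypermethylated-fraction matrix of the default cohort."""
    return pivot_fractions(fraction_matrix(default_cohort.ct))
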