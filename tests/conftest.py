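import numpy as np
import pytest

from asekit import SimulationConfig, load_reference_allelotype, simulate_cohort


@pytest.fixture(scope="session")
def reference_table():
    """Published per-sample/stratum allelotype summaries for rs386770867."""
    return load_reference_allelotype()


@pytest.fixture(scope="session")
def study_cohort():
    """One simulated cohort under the default study conditions."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort without outlier shocks or between-sample effect spread."""
    config = SimulationConfig(
        ase_effect_sd_log=0.0, outlier_prob=0.0, seed=7
    )
    return simulate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
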