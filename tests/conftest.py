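import numpy as np
import pytest

from urispec import (CohortConfig, default_marker_profiles, generate_cohort,
                     single_band_marker)


@pytest.fixture(scope="session")
def small_cohort():
    """Default marker battery, 40 patients — shared read-only fixture."""
    return generate_cohort(CohortConfig(n_patients=40, seed=7),
                           default_marker_profiles())


@pytest.fixture(scope="session")
def band_cohort():
    """Single 426-nm-band quantitative marker, 130 patients."""
    return generate_cohort(CohortConfig(n_patients=130, seed=0),
                           [single_band_marker()])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
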