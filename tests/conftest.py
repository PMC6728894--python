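import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny two-group cohort reused by several suites (6 + 6 subjects)."""
    from fcgraph import CohortSpec, simulate_cohort

    spec = CohortSpec(
        n_group_a=6, n_group_b=6, n_rois=40, n_timepoints=120,
        n_modules=4, clustering_deficit=0.3, duration_effect=0.03, seed=42,
    )
    records, covariates = simulate_cohort(spec)
    return spec, records, covariates
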