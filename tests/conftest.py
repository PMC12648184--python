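import numpy as np
import pytest

from connpred.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort (N=12, P=5, parcel 2 carries signal)."""
    cfg = CohortConfig(
        n_participants=12,
        n_parcels=5,
        n_timepoints=120,
        n_voxels=60,
        signal_parcels=frozenset({2}),
        effect_strength=0.8,
        master_seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
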