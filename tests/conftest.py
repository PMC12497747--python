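import numpy as np
import pytest

from monoconn.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def toy_cohort():
    """A small two-group cohort shared by pipeline-level tests."""
    cfg = SynthConfig(
        n_regions=8,
        n_participants_per_group=3,
        hub_nodes=frozenset({0}),
        drift_per_iteration=0.05,
        seed=1234,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(987)
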