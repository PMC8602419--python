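import numpy as np
import pytest

from soctwin.synthetic_data import SimulationConfig, TraitSpec, simulate_cohort


def ae_config(n_mz=500, n_dzss=500, n_dzos=0, a2=0.5, seed=0, **kw):
    """Single-trait AE cohort configuration on the standardized scale."""
    return SimulationConfig(n_mz, n_dzss, n_dzos,
                            {"y": TraitSpec.symmetric(0.0, 1.0, a2)},
                            seed=seed, **kw)


@pytest.fixture
def small_cohort():
    """254/176/156-pair AE cohort with a2 = 0.5 on trait 'y'."""
    return simulate_cohort(ae_config(254, 176, 156, a2=0.5, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20210519)
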