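import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from coclustsurv.cohort import GeneratorConfig, generate_cohort


def high_snr_config(seed: int, **overrides) -> GeneratorConfig:
    """The sharp-recovery fixture: block separation / noise = 4, n = 150."""
    kwargs = dict(
        n_patients=150,
        n_features_pet=40,
        n_features_ct=20,
        k_s=3,
        k_f=4,
        block_mean_separation=2.0,
        noise_sd=0.5,
        hazard_multipliers=(1.0, 2.0, 4.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def noiseless_config(seed: int, **overrides) -> GeneratorConfig:
    """Exact block matrix: 60 x 40, three patient and four feature groups."""
    kwargs = dict(
        n_patients=60,
        n_features_pet=30,
        n_features_ct=10,
        k_s=3,
        k_f=4,
        noise_sd=0.0,
        hazard_multipliers=(1.0, 2.0, 4.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(seed=123))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for cheap pipeline tests."""
    return generate_cohort(
        GeneratorConfig(n_patients=60, n_features_pet=24, n_features_ct=12,
                        k_s=3, k_f=4, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
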