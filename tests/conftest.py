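import warnings

import numpy as np
import pytest
from hypothesis import settings

import salivadx as dx

# sklearn 1.8 deprecation chatter from explicit penalty= keeps test logs clean
warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_planted_cohort():
    """20v20 cohort, 60+90 features, strong planted effect; shared across tests."""
    spec = dx.CohortSpec(
        n_cases=20,
        n_controls=20,
        n_species=60,
        n_kos=90,
        n_discriminative_species=3,
        n_discriminative_kos=3,
        effect_size=2 * np.log(2),
        depth_mean=50_000,
        zero_fraction=0.5,
        zero_fraction_ko=0.4,
        seed=42,
    )
    species, kos, meta, truth = dx.generate_cohort(spec)
    labels = dx.metadata_frame(meta)["label"]
    return spec, species, kos, meta, labels, truth


@pytest.fixture(scope="session")
def small_clr_pair(small_planted_cohort):
    _, species, kos, _, labels, truth = small_planted_cohort
    return dx.clr_transform(species), dx.clr_transform(kos), labels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
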