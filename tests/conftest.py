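import numpy as np
import pytest

from hemil import synthetic_cohort as sc


@pytest.fixture(scope="session")
def small_config() -> sc.CohortConfig:
    """A quick cohort: clear class separation, mild heterogeneity."""
    return sc.CohortConfig(
        n_patients=120, seed=7, feature_dim=32, regions_per_core=6,
        effect_size=3.0, heterogeneity=0.1,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sc.generate_cohort(small_config)


@pytest.fixture(scope="session")
def core_image(small_cohort):
    record = small_cohort[0]
    return sc.synthesize_core_image(record, side_px=256, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
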