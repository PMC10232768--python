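import numpy as np
import pytest

from painmap.cohort import CohortConfig, generate_cohort, make_block_atlas


def small_config(**overrides) -> CohortConfig:
    """A fast cohort: short runs, 8 regions on a small grid, no motion run."""
    base = dict(
        n_subjects=8,
        shape=(18, 18, 8),
        n_regions=8,
        planted_rois=(1, 2, 3),
        tracking_s=200.0,
        resting_s=180.0,
        include_motion=False,
        seed=0,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def atlas():
    return make_block_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    subjects, atl = generate_cohort(cfg)
    return cfg, subjects, atl


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
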