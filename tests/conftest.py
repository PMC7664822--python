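import numpy as np
import pytest

from nodtex import (
    SyntheticCohortConfig,
    build_feature_matrix,
    generate_cohort,
    generate_nodule,
)


@pytest.fixture(scope="session")
def small_cfg():
    """A small, fast cohort configuration for unit tests."""
    return SyntheticCohortConfig(
        n_class_nch=3, n_class_aca=3, volume_shape=(48, 48, 48),
        diameter_mean_sd_nch=(14.0, 3.0), diameter_mean_sd_aca=(20.0, 3.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def nch_lesion(small_cfg):
    return generate_nodule(small_cfg, "nch", seed=101)


@pytest.fixture(scope="session")
def aca_lesion(small_cfg):
    return generate_nodule(small_cfg, "aca", seed=202)


@pytest.fixture(scope="session")
def small_matrix(small_cfg):
    """Feature matrix of the small 3+3 cohort."""
    lesions, _ = generate_cohort(small_cfg)
    return build_feature_matrix(lesions)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
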