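import numpy as np
import pytest

from dkitex import PhantomSpec, generate_phantom_cohort
from dkitex.classification import SMALL_C_GRID, SMALL_GAMMA_GRID, SvmConfig
from dkitex.pipeline import extract_feature_table


@pytest.fixture(scope="session")
def small_svm_config():
    """Compact hyperparameter grid for simulation-scale experiments."""
    return SvmConfig(c_grid=SMALL_C_GRID, gamma_grid=SMALL_GAMMA_GRID, seed=0)


@pytest.fixture(scope="session")
def small_phantom_cohort():
    """A small two-class phantom cohort with a DKI-only class signal."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 10),
        n_subjects_per_class=(8, 6),
        voi_radius=8.0,
        voi_radius_jitter=1.0,
        seed=11,
    )
    return generate_phantom_cohort(spec)


@pytest.fixture(scope="session")
def small_phantom_features(small_phantom_cohort):
    """Extracted biomarker table for the small phantom cohort."""
    return extract_feature_table(cohort=small_phantom_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
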