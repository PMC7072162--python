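import numpy as np
import pytest

from prostarad.grid import VolumeGrid
from prostarad.phantom import CohortSpec, generate_cohort
from prostarad.pipeline import cohort_feature_table, cohort_maps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(**overrides) -> CohortSpec:
    """A desk-size cohort for unit tests: same structure, smaller grids."""
    kw = dict(
        n_subjects=5,
        n_lesion_vois=5,
        n_ht_vois=4,
        t2w_grid=VolumeGrid((24, 24, 10), (2.0, 2.0, 3.0)),
        dwi_grid=VolumeGrid((12, 12, 10), (4.0, 4.0, 3.0)),
        dce_grid=VolumeGrid((12, 12, 10), (4.0, 4.0, 3.0)),
        voi_axes_mm=(4.0, 8.0),
        voi_axes_z_mm=(3.0, 6.0),
        seed=7,
    )
    kw.update(overrides)
    return CohortSpec(**kw)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(small_spec())


@pytest.fixture(scope="session")
def tiny_maps(tiny_cohort):
    return cohort_maps(tiny_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size study conditions: 65 subjects, 69 lesion + 49 healthy
    VOIs, the acquisition b-value scheme and 60-phase dynamic series."""
    return generate_cohort(CohortSpec(seed=20200207))


@pytest.fixture(scope="session")
def std3d_table(default_cohort):
    """std3D feature table (44 features + label) of the default cohort."""
    return cohort_feature_table(default_cohort, "std3D")
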