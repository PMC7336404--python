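import numpy as np
import pytest

from glioradiomics.core import ImageVolume, LabelMask
from glioradiomics.io_cli import extract_cohort_features
from glioradiomics.synthdata import CohortConfig, generate_cohort


def make_mask(values, spacing=(1.0, 1.0, 1.0)) -> LabelMask:
    return LabelMask(np.asarray(values, dtype=bool), spacing)


def make_volume(values, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(np.asarray(values, dtype=np.float64), spacing)


def cube_mask(n, grid=None, spacing=(1.0, 1.0, 1.0)) -> LabelMask:
    """Solid n-cube embedded centrally in a (grid)^3 lattice."""
    g = grid if grid is not None else n + 4
    arr = np.zeros((g, g, g), dtype=bool)
    o = (g - n) // 2
    arr[o : o + n, o : o + n, o : o + n] = True
    return make_mask(arr, spacing)


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-subject default-parameter cohort shared across tests."""
    cfg = CohortConfig(n_subjects=16, seed=7)
    cases, manifest = generate_cohort(cfg)
    return cfg, cases, manifest


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, cases, manifest = small_cohort
    return extract_cohort_features(cases, manifest)
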