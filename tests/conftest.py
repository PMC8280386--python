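import numpy as np
import pytest

from lungseg.phantom import PhantomParams, make_thorax_slice


@pytest.fixture(scope="session")
def clean_slice():
    """Severity-0, noise-free nominal-contrast slice with its ground truth."""
    return make_thorax_slice(
        PhantomParams(seed=11, pathology_severity=0.0, noise_sigma=0.0))


@pytest.fixture(scope="session")
def broken_slice():
    """Same geometry seed with pathology-disrupted lung contours."""
    return make_thorax_slice(
        PhantomParams(seed=11, pathology_severity=0.4, noise_sigma=0.0))


@pytest.fixture(scope="session")
def nonlung_slice():
    return make_thorax_slice(
        PhantomParams(seed=12, lung_present=False, noise_sigma=0.0))


def disk(radius, size=None, center=None):
    size = size or int(2 * radius + 11)
    center = center or (size // 2, size // 2)
    r, c = np.mgrid[0:size, 0:size]
    return (((r - center[0]) ** 2 + (c - center[1]) ** 2) <= radius**2).astype(np.uint8)
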