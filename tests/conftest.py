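import numpy as np
import pytest

from flpet import (
    LesionSpec,
    PhantomSpec,
    SegmentationConfig,
    feature_panel,
    make_phantom,
    segment_lesions,
)
from flpet.segmentation import lesion_set_from_labels


@pytest.fixture
def rng():
    return np.random.default_rng(20240405)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noise-free digitized sphere r = 20 mm at 1 mm spacing, plateau SUV 10."""
    spec = PhantomSpec(
        shape=(56, 56, 56),
        spacing=(1.0, 1.0, 1.0),
        background_suv=0.5,
        noise_sd=0.0,
        lesions=[LesionSpec(shape="sphere", center_mm=(27.0, 27.0, 27.0), size_mm=20.0, peak_suv=10.0)],
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def sphere_panel(sphere_phantom):
    vol, _, _ = sphere_phantom
    _, lesions = segment_lesions(vol)
    return feature_panel(vol, lesions)


def random_lesion_set(rng, n_lesions=2, grid=16, spacing=(1.0, 1.0, 1.0), max_voxels=500):
    """A random small multi-lesion set for oracle-equivalence checks."""
    from flpet.segmentation import label_components

    binary = np.zeros((grid, grid, grid), dtype=bool)
    for _ in range(n_lesions):
        center = rng.integers(3, grid - 3, size=3)
        n_steps = int(rng.integers(10, max_voxels // n_lesions))
        p = center.copy()
        for _ in range(n_steps):
            binary[tuple(np.clip(p, 0, grid - 1))] = True
            p = p + rng.integers(-1, 2, size=3)
    labels, _ = label_components(binary, 26)
    suv = rng.uniform(1.0, 10.0, size=binary.shape)
    suv[~binary] = 0.0
    return lesion_set_from_labels(labels, spacing, suv), suv
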