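import numpy as np
import pytest

from dvaseg import BinaryMask, StyleSpec, generate_cohort


def random_mask_pair(rng, max_shape=(12, 12, 4)):
    """A random pair of same-grid masks with anisotropic spacing."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    spacing = tuple(float(rng.uniform(0.5, 3.0)) for _ in range(3))
    a = rng.random(shape) < rng.uniform(0.2, 0.8)
    b = rng.random(shape) < rng.uniform(0.2, 0.8)
    return (BinaryMask(a.astype(np.uint8), spacing),
            BinaryMask(b.astype(np.uint8), spacing))


@pytest.fixture(scope="session")
def two_style_specs():
    return [StyleSpec(0, polar_offset_mm=2.0, noise_sd_mm=0.3),
            StyleSpec(1, polar_offset_mm=-2.0, noise_sd_mm=0.3)]


@pytest.fixture(scope="session")
def tiny_cohort(two_style_specs):
    """8 train / 2 val / 2 test scans for oracle tests.

    Balanced by design: 4+4 styles in training and both styles in
    validation, so only the style-pure grouping attains the oracle optimum.
    """
    return generate_cohort(12, two_style_specs, [0.5, 0.5], (8, 2, 2), seed=1,
                           min_style_counts={"train": 4, "val": 1})


@pytest.fixture(scope="session")
def small_train_cohort(two_style_specs):
    """A small cohort for real (non-oracle) training tests."""
    return generate_cohort(9, two_style_specs, [0.5, 0.5], (6, 2, 1), seed=21)
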