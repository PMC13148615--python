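"""Shared fixtures: a small bench geometry and reusable simulated scenes.

Everything is generated programmatically at collection time; heavy objects
are session-scoped so the expensive simulations run once.
"""

import numpy as np
import pytest

from mobi import AcquisitionGeometry, ExperimentConfig
from mobi.experiments import build_mask, _acquire


@pytest.fixture(scope="session")
def geometry() -> AcquisitionGeometry:
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def small_cfg() -> ExperimentConfig:
    """128 px field, warp model: fast generative oracle for retrieval tests."""
    return ExperimentConfig(field_shape=(128, 128), seed=42, model="warp",
                            oversample=2)


@pytest.fixture(scope="session")
def spiral_mask(small_cfg):
    return build_mask(small_cfg, "spiral")


@pytest.fixture(scope="session")
def reference_series(small_cfg, spiral_mask):
    """K=6 reference-only series (no sample), with noise."""
    return _acquire(small_cfg, spiral_mask, None, tag=900)


@pytest.fixture(scope="session")
def smooth_pattern_stack():
    """K smooth synthetic reference patterns (band-limited noise),
    independent of the imaging pipeline."""
    from scipy import ndimage

    rng = np.random.default_rng(123)
    K, H, W = 8, 96, 96
    pats = []
    for _ in range(K):
        p = ndimage.gaussian_filter(rng.normal(size=(H, W)), 1.5)
        pats.append(1000.0 * (1.0 + 0.5 * p / np.abs(p).max()))
    return np.stack(pats)
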