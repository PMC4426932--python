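"""Shared fixtures: small, fast synthetic configurations.

The reduced EPID (256 px at 1.6 mm/px) preserves the isocenter-scale
coverage of the full 1024-px panel while keeping image generation cheap;
geometry-sensitive checks use the full-resolution panel directly.
"""

import numpy as np
import pytest

from gacdose import SyntheticConfig, make_abutment_grid


@pytest.fixture(scope="session")
def small_config():
    """Noise-free reduced-resolution EPID configuration."""
    return SyntheticConfig(
        seed=11, epid_pixels=256, epid_pitch=1.6, noise_sigma_pct=0.0
    )


@pytest.fixture(scope="session")
def default_grid():
    return make_abutment_grid()


@pytest.fixture(scope="session")
def zero_delta_r(default_grid):
    shape = (default_grid.leaf_indices.size, default_grid.abutment_x.size)
    return {0.0: np.zeros(shape)}
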