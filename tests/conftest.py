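import numpy as np
import pytest

from spheroquant import SectionSpec, SpheroidMask


@pytest.fixture
def disk_mask():
    """Perfect disk of radius 80 px centered in a 201x201 field."""
    yy, xx = np.mgrid[:201, :201]
    return SpheroidMask((yy - 100) ** 2 + (xx - 100) ** 2 <= 80**2)


@pytest.fixture
def small_disk_mask():
    """Radius-25 disk in a 64x64 field, for brute-force comparisons."""
    yy, xx = np.mgrid[:64, :64]
    return SpheroidMask((yy - 32) ** 2 + (xx - 32) ** 2 <= 25**2)


def star_convex_spec(seed, size=128, radius=40.0, irregularity=0.2):
    """Spec for a random star-convex mask (via the bright-field renderer)."""
    return SectionSpec(seed=seed, image_size=(size, size), radius=radius,
                       boundary_irregularity=irregularity)
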