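import os
import tempfile

import numpy as np
import pytest
from hypothesis import configuration, settings

from gliaquant import GroupSpec

# keep hypothesis caches out of the repository
configuration.set_hypothesis_home_dir(
    os.path.join(tempfile.gettempdir(), "hypothesis_home"))
settings.register_profile("no_db", database=None)
settings.load_profile("no_db")

# Small-FOV rendering used by image-level unit tests: 250 px at 0.43 um/px.
SMALL_FOV_UM = 107.5
PX = 0.43


@pytest.fixture
def small_plaque_spec():
    """A plaque-only group scaled to the small test FOV."""
    return GroupSpec("test_plaques", plaque_density=5.0,
                     plaque_diameter_dist=(16.0, 0.25),
                     microglia_base_density=0.0, pa_recruitment_coeff=0.0)


@pytest.fixture
def small_microglia_spec():
    """A microglia-only group scaled to the small test FOV."""
    return GroupSpec("test_microglia", plaque_density=0.0,
                     microglia_base_density=8.0, pa_recruitment_coeff=0.0)


def disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
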