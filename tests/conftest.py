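import numpy as np
import pytest

from rhizopan.acquisition import AcquisitionPlan
from rhizopan.synthetic import (ReflectionParams, acquire, default_camera,
                                generate_scene)

# Shared small study scene: prototype geometry (63.5 mm tube, 60° lens at
# 40% overlap, 15 mm steps) over a 75 mm window -> 5 strips x 10 snaps.


@pytest.fixture(scope="session")
def plan75():
    return AcquisitionPlan(tube_len_mm=75.0)


@pytest.fixture(scope="session")
def scene75():
    return generate_scene(tube_len_mm=75.0, seed=7)


@pytest.fixture(scope="session")
def camera_clean(scene75, plan75):
    return default_camera(scene75, plan75)


@pytest.fixture(scope="session")
def camera_streaks(scene75, plan75):
    return default_camera(scene75, plan75,
                          reflection=ReflectionParams(n_streaks=2))


@pytest.fixture(scope="session")
def snaps_clean(scene75, plan75, camera_clean):
    snaps, records = acquire(scene75, plan75, camera_clean, seed=3)
    return snaps, records


@pytest.fixture(scope="session")
def truth_aligned(scene75, plan75, camera_clean):
    """Ground truth in panorama alignment (columns start at -18°)."""
    shift = int(round(360.0 / plan75.snaps_per_rotation / 2
                      * scene75.px_per_deg))
    return np.roll(scene75.texture, shift, axis=1)
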