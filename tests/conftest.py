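import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from PIL import Image

import ncarkit as nk

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def small_plate_spec():
    """100x100 plate: dish r=40 at 120, concentric colony r=20 at 240, dark bg."""
    return nk.PlateSpec(
        image_size=100,
        dish_center=(50.0, 50.0),
        dish_radius=40.0,
        colony_center=(50.0, 50.0),
        colony_radius=20.0,
        intensities=(10, 120, 240),
    )


@pytest.fixture
def png_factory(tmp_path):
    """Write an arbitrary uint8 array (2-D gray or HxWx3 RGB) as a PNG."""

    def write(arr, name="plate.png"):
        arr = np.asarray(arr, dtype=np.uint8)
        mode = "L" if arr.ndim == 2 else "RGB"
        path = tmp_path / name
        Image.fromarray(arr, mode=mode).save(path)
        return path

    return write


def brute_force_disk_count(size, center, radius):
    """Independent O(N^2) pixel-centre enumeration of a discrete disk."""
    cx, cy = center
    count = 0
    for i in range(size):
        for j in range(size):
            if (j + 0.5 - cx) ** 2 + (i + 0.5 - cy) ** 2 <= radius**2:
                count += 1
    return count
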