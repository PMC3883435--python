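import numpy as np
import pytest

from chipcode import (
    PlateImage,
    PlateLayout,
    RoiSpec,
    WellAddress,
    WellAssignment,
    default_layout,
)


@pytest.fixture(scope="session")
def layout96():
    """The shipped default 96-well layout (8 sensors x 2 conditions x 3 assays)."""
    return default_layout()


@pytest.fixture()
def tiny_layout():
    """Smallest legal layout: one control/analyte pair of DC1 under condition 1."""
    return PlateLayout(
        n_rows=1,
        n_cols=2,
        origin_x=10,
        origin_y=10,
        pitch_x=20,
        pitch_y=20,
        roi=RoiSpec("disk", 3),
        well_map={
            WellAddress("A", 1): WellAssignment("DC1", 1, "control", "P01"),
            WellAddress("A", 2): WellAssignment("DC1", 1, "analyte", "P01"),
        },
    )


def make_uniform_image(h, w, rgb, dtype=np.uint8):
    px = np.empty((h, w, 3), dtype=dtype)
    px[:, :] = rgb
    return PlateImage(px, 8 if dtype == np.uint8 else 16)


@pytest.fixture()
def uniform_white():
    return make_uniform_image(40, 60, (255, 255, 255))


@pytest.fixture()
def uniform_black():
    return make_uniform_image(40, 60, (0, 0, 0))
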