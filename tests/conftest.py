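import numpy as np
import pytest

from mifquant import default_panel, make_default_library, render_tissue_image
from mifquant.synth_images import place_random_cells

PIXEL_SIZE = 0.496


@pytest.fixture(scope="session")
def library():
    return make_default_library(10, seed=1)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def noiseless_scene(library):
    """40 non-overlapping cells rendered without noise, with ground truth."""
    shape = (320, 320)
    cells = place_random_cells(40, shape, PIXEL_SIZE, seed=11)
    image, truth = render_tissue_image(
        cells, library, shape, PIXEL_SIZE, autofluorescence_level=0.1,
        noise_sd=0.0, seed=12,
    )
    return cells, image, truth
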