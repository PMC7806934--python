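import numpy as np
import pytest

from lymphoscreen import ImageSimConfig, IntensityLaw, QuantConfig


@pytest.fixture
def noiseless_config() -> ImageSimConfig:
    """A field whose planted blobs all fall strictly inside the capture and
    positivity ranges, with zero background noise: the ground-truth oracle
    setting for the quantification chain."""
    return ImageSimConfig(
        field_width_px=512,
        field_height_px=512,
        n_cells=40,
        positive_fraction=0.4,
        radius_range_um=(5.0, 12.0),
        intensity_law_red=IntensityLaw("uniform", (170.0, 250.0)),
        intensity_law_green=IntensityLaw("uniform", (170.0, 250.0)),
        intensity_law_blue=IntensityLaw("uniform", (170.0, 250.0)),
        background_noise_sd=0.0,
        seed=11,
    )


@pytest.fixture
def quant_config() -> QuantConfig:
    return QuantConfig()


def draw_disk(radius_px: float, grey: float, size: int = 256) -> np.ndarray:
    """Single centred uniform disk on a zero background."""
    from skimage.draw import disk

    img = np.zeros((size, size), dtype=np.uint8)
    rr, cc = disk((size // 2, size // 2), radius_px, shape=(size, size))
    img[rr, cc] = int(grey)
    return img
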