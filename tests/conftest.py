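import numpy as np
import pytest

from punctascreen import ChannelImage, SceneSpec, SegmentationParams
from punctascreen.synthetic import FWHM_PER_SIGMA, _add_gaussian_spot


@pytest.fixture
def params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture
def noise_free_spec() -> SceneSpec:
    return SceneSpec(
        field_size_px=(512, 512),
        n_cells=5,
        noise_sd=0.0,
        background_gradient_amplitude=0.0,
        seed=11,
    )


def render_spot(
    shape: tuple[int, int],
    width_um: float,
    amplitude: float = 500.0,
    center: tuple[float, float] | None = None,
    pixel_size_um: float = 0.325,
    base: float = 0.0,
) -> ChannelImage:
    """A single Gaussian spot of the given full width at half maximum."""
    img = np.full(shape, base, dtype=float)
    if center is None:
        center = (shape[0] / 2 - 0.3, shape[1] / 2 + 0.2)
    sigma = width_um / pixel_size_um / FWHM_PER_SIGMA
    _add_gaussian_spot(img, center[0], center[1], sigma, amplitude)
    return ChannelImage(img, "spot", pixel_size_um)


def render_disc(
    shape: tuple[int, int],
    diameter_um: float,
    amplitude: float = 400.0,
    pixel_size_um: float = 0.325,
    base: float = 0.0,
) -> ChannelImage:
    """A single hard-edged disc of the given diameter."""
    img = np.full(shape, base, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r_px = diameter_um / pixel_size_um / 2.0
    cr, cc = shape[0] / 2, shape[1] / 2
    img[(yy - cr) ** 2 + (xx - cc) ** 2 <= r_px**2] += amplitude
    return ChannelImage(img, "disc", pixel_size_um)
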