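import numpy as np
import pytest

import ctiq


@pytest.fixture(scope="session")
def layout():
    """Full-size default phantom (512x512, 35x25 cm body)."""
    return ctiq.PhantomLayout()


@pytest.fixture(scope="session")
def small_layout():
    """Reduced phantom for fast simulation-heavy tests.

    Same pixel spacing and insert/lesion dimensions as the default layout,
    smaller body and grid.
    """
    return ctiq.PhantomLayout(grid_size=(256, 256), body_semiaxes_mm=(80, 70),
                              insert_center_mm=(-40, 0), lc_center_mm=(40, 0))


@pytest.fixture(scope="session")
def fbp_shape(small_layout):
    """Ramp-Gaussian NPS shape calibrated to f_avg = 0.30 mm^-1."""
    return ctiq.calibrate_shape(0.30, "fbp-like", small_layout.pixel_spacing)


@pytest.fixture(scope="session")
def noiseless_blurred_stack(small_layout):
    """Noiseless render blurred with a 0.6 mm Gaussian PSF (14 slices)."""
    model = ctiq.NoiseModel("noiseless", sigma_ref=0.0, edge_blur_sigma=0.6)
    return ctiq.simulate_scan(small_layout, model, 25.0, 2.5, 14, seed=0)
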