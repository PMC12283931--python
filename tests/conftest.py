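import numpy as np
import pytest
from hypothesis import settings

import tubemech as tm

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(1234)


@pytest.fixture
def noiseless_optics():
    """Unit pixel size, no shot/read noise: rendered geometry is exact."""
    return tm.OpticsConfig(
        pixel_size=1.0,
        psf_sigma=1.0,
        peak_intensity=200.0,
        background=10.0,
        read_noise_sd=0.0,
        shot_noise=False,
    )


def render_single(nodes, optics, field_size):
    """Render one trace (unit-pixel coordinates) into a single 8-bit frame."""
    trace = tm.FilamentTrace(0, 0, np.asarray(nodes, float), unit="um")
    stack = tm.TrackStack(0, (trace,))
    img = tm.render_frames(
        [stack], optics, np.random.default_rng(0), field_size=field_size
    )
    return trace, tm.to_8bit(img)[0]
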