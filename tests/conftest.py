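"""Shared fixtures: small LED geometries and scaled-down study frames.

Frame sizes used in tests are reduced from the full 4096x3000 sensor where
the property under test is size-independent; shift magnitudes and filter
parameters are kept at their full-scale values whenever the property
depends on their interplay.
"""

import copy

import numpy as np
import pytest

from spdri.config import DEFAULTS
from spdri.model import LedSpec, Side


@pytest.fixture(scope="session")
def instrument_leds():
    from spdri.model import load_instrument_leds

    return {led.led_id: led for led in load_instrument_leds()}


@pytest.fixture
def small_long_pair():
    """Two long-side LEDs 40 px apart, for compact frames."""
    a = LedSpec(led_id=1, side=Side.LONG_AXIS, position_px=150.0, intensity_uW=12.0)
    b = LedSpec(led_id=2, side=Side.LONG_AXIS, position_px=190.0, intensity_uW=5.1)
    return a, b


@pytest.fixture
def small_short_pair():
    a = LedSpec(led_id=4, side=Side.SHORT_AXIS, position_px=140.0, intensity_uW=12.4)
    b = LedSpec(led_id=5, side=Side.SHORT_AXIS, position_px=100.0, intensity_uW=1.6)
    return a, b


@pytest.fixture(scope="session")
def reduced_config():
    """Full-parameter configuration on a reduced frame.

    Wide enough for the instrument LED positions (x up to 2055 px) and the
    full-scale shift/filter geometry: along the shift axis a case needs the
    out-of-overlap band (up to 389 px), the detection border (shift + half
    the filter window) on both sides, and the thread features in between.
    The short-side pair is recentered by the pipeline while its 389 px
    shift is preserved. Treated as read-only; tests that mutate it copy it.
    """
    cfg = copy.deepcopy(DEFAULTS)
    cfg["frame"]["height_px"] = 2200
    cfg["frame"]["width_px"] = 2600
    return cfg


@pytest.fixture(scope="session")
def demo_report_default_scale():
    """One full-scale demonstration run shared by the acceptance tests."""
    from spdri.config import load_config
    from spdri.pipeline import run_demo

    return run_demo(load_config(), seed=20, out_dir=None)


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """The truncated discrete Gaussian kernel used by scipy.ndimage
    (truncate = 4), rebuilt independently for convolution oracles."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * x**2 / sigma**2)
    return phi / phi.sum()
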