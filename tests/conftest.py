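import numpy as np
import pytest

from tma_dearray.io_preprocess import IntensityImage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def render_disk(shape, center, radius, value=1.0, background=0.0, supersample=4):
    """Anti-aliased disk on a constant background (independent of synth)."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    cov = np.zeros((H, W))
    for dy in offs:
        for dx in offs:
            cov += ((xx + dx - center[0]) ** 2 + (yy + dy - center[1]) ** 2) <= radius**2
    cov /= supersample**2
    return background + (value - background) * cov


def render_ellipse(shape, center, a, b, theta, value=1.0, background=0.0, supersample=4):
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    c, s = np.cos(theta), np.sin(theta)
    cov = np.zeros((H, W))
    for dy in offs:
        for dx in offs:
            px, py = xx + dx - center[0], yy + dy - center[1]
            u1 = (c * px + s * py) / a
            u2 = (-s * px + c * py) / b
            cov += (u1 * u1 + u2 * u2) <= 1.0
    cov /= supersample**2
    return background + (value - background) * cov


@pytest.fixture
def disk_image():
    """One bright disk of radius 15 centered in a 101x101 frame."""
    return IntensityImage(render_disk((101, 101), (50, 50), 15.0), modality="binary")
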