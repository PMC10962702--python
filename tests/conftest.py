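import numpy as np
import pytest

from hifish import GrayImage, LabelMask, SimulationConfig, simulate_field


def disk_mask(radius: int, pad: int = 10, pixel_size: float = 0.108) -> LabelMask:
    """A single rasterized disk nucleus (label 1) centered in the frame."""
    n = 2 * radius + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    c = n // 2
    labels = (((yy - c) ** 2 + (xx - c) ** 2) <= radius * radius).astype(np.int32)
    return LabelMask(labels, pixel_size)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def textured_nuclei_image(rng):
    """A DAPI-like image with structured content for registration tests."""
    cfg = SimulationConfig(seed=7, image_size=256, n_nuclei=2,
                           nucleus_radius_range=(28, 34), pixel_size=0.216)
    acqs, _ = simulate_field(cfg)
    return acqs[0]["DAPI"]


@pytest.fixture
def small_field():
    """One simultaneous field with known ground truth (3 nuclei)."""
    cfg = SimulationConfig(seed=11, image_size=420, n_nuclei=3,
                           nucleus_radius_range=(50, 56), p_active=0.5)
    return simulate_field(cfg)


def gray(arr, pixel_size=0.108) -> GrayImage:
    return GrayImage(np.asarray(arr, dtype=float), pixel_size)
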