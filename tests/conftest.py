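"""Shared fixtures: small rendered scenes, reused across test modules."""

import math

import numpy as np
import pytest
from skimage import draw

from paniclekit.calibration import RasterImage, detect_reference_disk
from paniclekit.counting import DensityClass
from paniclekit.preprocess import segment_panicle
from paniclekit.synthetic import GRAIN_SHADING, PanicleSpec, generate_panicle


def render_grains(grains, hw=(200, 200), color=(200, 175, 65), background=12, noise_seed=0):
    """Render shaded ellipses ``(row, col, a, b, theta)`` on a dark field."""
    canvas = np.full((*hw, 3), float(background))
    rng = np.random.default_rng(noise_seed)
    for cr, cc, a, b, theta in grains:
        rr, cc2 = draw.ellipse(cr, cc, b, a, shape=hw, rotation=-theta)
        dy, dx = rr - cr, cc2 - cc
        along = dy * math.sin(theta) + dx * math.cos(theta)
        across = dy * math.cos(theta) - dx * math.sin(theta)
        rho2 = np.clip((along / a) ** 2 + (across / b) ** 2, 0, 1)
        canvas[rr, cc2] = np.asarray(color, float) * (1 - GRAIN_SHADING * rho2)[:, None]
    canvas += rng.normal(0, 2, canvas.shape)
    return RasterImage(np.clip(canvas, 0, 255).astype(np.uint8), "rendered")


@pytest.fixture(scope="session")
def loose_scene():
    """One loose synthetic panicle with calibration and mask precomputed."""
    img, gt = generate_panicle(PanicleSpec(seed=11, density=DensityClass.LOOSE))
    cal = detect_reference_disk(img)
    mask = segment_panicle(img, cal)
    return img, gt, cal, mask


@pytest.fixture(scope="session")
def dense_scene():
    img, gt = generate_panicle(PanicleSpec(seed=11, density=DensityClass.DENSE))
    cal = detect_reference_disk(img)
    mask = segment_panicle(img, cal)
    return img, gt, cal, mask
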