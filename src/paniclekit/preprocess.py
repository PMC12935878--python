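"""Binary panicle segmentation: grayscale, denoise, Otsu, closing.

The imaging protocol photographs a single panicle on a uniform dark
background, so a global Otsu threshold on the denoised luma separates
panicle from background; morphological closing then bridges small gaps
between thin branches and fills pinholes. The calibration disk, if
located, is blanked from the foreground so it never contaminates the
skeleton or grain statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .calibration import RasterImage, ScaleCalibration
from .errors import DomainError, SegmentationError

__all__ = ["SegmentConfig", "to_grayscale", "denoise", "segment_panicle", "save_mask"]

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class SegmentConfig:
    close_radius_px: int = 3
    min_area_px: int = 500
    denoise_method: str = "median"  # "median" | "gaussian"
    denoise_radius: int = 2
    invert: bool = False  # True for a dark panicle on a bright background


def to_grayscale(img: RasterImage) -> np.ndarray:
    """Luma ``0.299 R + 0.587 G + 0.114 B`` on [0, 1]-scaled channels."""
    return (img.pixels.astype(np.float64) / 255.0) @ LUMA_WEIGHTS


def denoise(gray: np.ndarray, method: str = "median", radius: int = 2) -> np.ndarray:
    """Median or Gaussian smoothing with a disk-shaped neighbourhood."""
    if radius < 1:
        raise DomainError(f"denoise radius must be >= 1, got {radius}")
    if method == "median":
        footprint = morphology.disk(radius)
        return ndi.median_filter(gray, footprint=footprint)
    if method == "gaussian":
        return ndi.gaussian_filter(gray, sigma=radius)
    raise DomainError(f"unknown denoise method {method!r}")


def segment_panicle(
    img: RasterImage,
    cal: ScaleCalibration | None = None,
    cfg: SegmentConfig | None = None,
) -> np.ndarray:
    """Segment the panicle into a boolean foreground mask.

    Pipeline: luma -> denoise -> Otsu threshold -> closing (disk
    structuring element) -> small-component removal -> blank the
    calibration-disk region. Raises :class:`SegmentationError` when the
    foreground is empty after filtering ("no panicle found").
    """
    cfg = cfg or SegmentConfig()
    gray = denoise(to_grayscale(img), cfg.denoise_method, cfg.denoise_radius)
    if np.ptp(gray) <= 1e-12:
        raise SegmentationError("no panicle found (uniform image)")
    # three-class Otsu, keeping the lower cut: the scene has background,
    # dull rachis, and bright grains; a plain two-class threshold drifts
    # up between rachis and grains when the grains are very bright and
    # severs the rachis from the mask
    try:
        thresh = float(filters.threshold_multiotsu(gray, classes=3)[0])
    except ValueError:  # fewer than 3 distinct levels
        thresh = float(filters.threshold_otsu(gray))
    mask = gray < thresh if cfg.invert else gray > thresh

    if cal is not None and np.isfinite(cal.disk_radius_px):
        rr, cc = np.ogrid[: mask.shape[0], : mask.shape[1]]
        cr, ccenter = cal.disk_center
        pad = cal.disk_radius_px * 1.15 + 2  # margin for blur halo
        mask &= (rr - cr) ** 2 + (cc - ccenter) ** 2 > pad**2

    mask = morphology.closing(mask, morphology.disk(cfg.close_radius_px))
    # fill enclosed holes: keeps the foreground simply connected, so the
    # downstream skeleton is a tree rather than a graph riddled with loops
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=cfg.min_area_px - 1, connectivity=2)
    if not mask.any():
        raise SegmentationError("no panicle found")
    return mask


def save_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit PNG (foreground = 255)."""
    import imageio.v3 as iio

    iio.imwrite(path, (mask.astype(np.uint8) * 255))
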