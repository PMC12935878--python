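"""Scale calibration from a red circular reference disk.

Panicle photographs include a red disk of known physical diameter
(30 mm by default) lying in the scene. Locating the disk and measuring
its pixel radius yields the mm-per-pixel conversion factor used by every
metric downstream (panicle length, grain length/width).

Coordinates are (row, col), 0-based; boxes are half-open
``[r0, r1) x [c0, c1)`` throughout the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .errors import CalibrationError, DomainError, InputFormatError

__all__ = [
    "RasterImage",
    "ScaleCalibration",
    "load_image",
    "detect_reference_disk",
    "px_to_mm",
]

#: Physical diameter of the reference disk shipped with the imaging rig.
DEFAULT_REF_DIAMETER_MM = 30.0

# Red-dominance rule: R >= RED_RATIO * G, R >= RED_RATIO * B and R >= RED_MIN.
RED_RATIO = 1.5
RED_MIN = 80
CIRCULARITY_MIN = 0.75
RED_FRACTION_MIN = 0.6
#: Two candidates whose scores differ by less than this are "ambiguous".
AMBIGUITY_MARGIN = 0.02


@dataclass(frozen=True)
class RasterImage:
    """An 8-bit sRGB image in (H, W, 3) row-major layout, channels R,G,B."""

    pixels: np.ndarray
    path: str = "<memory>"

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputFormatError(
                f"{self.path}: not a 3-channel image (shape {px.shape})"
            )
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise InputFormatError(
                f"{self.path}: image smaller than 32x32 ({px.shape[0]}x{px.shape[1]})"
            )
        if px.dtype != np.uint8:
            raise InputFormatError(f"{self.path}: expected uint8 pixels, got {px.dtype}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-millimetre conversion derived from the reference disk.

    ``mm_per_px = ref_diameter_mm / (2 * disk_radius_px)``.
    """

    mm_per_px: float
    disk_center: tuple[float, float] = (math.nan, math.nan)
    disk_radius_px: float = math.nan
    ref_diameter_mm: float = field(default=DEFAULT_REF_DIAMETER_MM)

    def __post_init__(self) -> None:
        if not (self.mm_per_px > 0 and math.isfinite(self.mm_per_px)):
            raise DomainError(f"mm_per_px must be finite and > 0, got {self.mm_per_px}")

    @classmethod
    def from_mm_per_px(cls, mm_per_px: float) -> "ScaleCalibration":
        """A calibration supplied directly (no disk in the scene)."""
        return cls(mm_per_px=mm_per_px)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mm_per_px": self.mm_per_px,
                "disk_center": list(self.disk_center),
                "disk_radius_px": self.disk_radius_px,
                "ref_diameter_mm": self.ref_diameter_mm,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScaleCalibration":
        d = json.loads(text)
        return cls(
            mm_per_px=d["mm_per_px"],
            disk_center=tuple(d["disk_center"]),
            disk_radius_px=d["disk_radius_px"],
            ref_diameter_mm=d["ref_diameter_mm"],
        )


def load_image(path: str | Path) -> RasterImage:
    """Read a PNG/JPEG/TIFF file into an R,G,B uint8 array.

    Raises :class:`InputFormatError` for unreadable files and for images
    that are not plain 3-channel colour (grayscale, CMYK, ...). An alpha
    channel, if present, is dropped.
    """
    import imageio.v3 as iio

    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise InputFormatError(f"{path}: cannot read image ({exc})") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputFormatError(f"{path}: not a 3-channel image (shape {arr.shape})")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return RasterImage(pixels=np.ascontiguousarray(arr), path=str(path))


def _red_mask(pixels: np.ndarray) -> np.ndarray:
    r = pixels[:, :, 0].astype(np.int32)
    g = pixels[:, :, 1].astype(np.int32)
    b = pixels[:, :, 2].astype(np.int32)
    return (r >= RED_RATIO * g) & (r >= RED_RATIO * b) & (r >= RED_MIN)


def detect_reference_disk(
    img: RasterImage, ref_diameter_mm: float = DEFAULT_REF_DIAMETER_MM
) -> ScaleCalibration:
    """Locate the red calibration disk and derive the mm-per-pixel factor.

    Candidate red connected components are scored by circularity
    (``4*pi*A / P**2``) times the red-pixel fraction inside the fitted
    circle; the best candidate passing both thresholds wins. The disk
    radius is the equivalent-area radius ``sqrt(A/pi)`` of the component,
    which is robust to single-pixel boundary noise.
    """
    if ref_diameter_mm <= 0:
        raise DomainError(f"ref_diameter_mm must be > 0, got {ref_diameter_mm}")
    red = _red_mask(img.pixels)
    labels = measure.label(red, connectivity=2)
    scored: list[tuple[float, float, tuple[float, float], float]] = []
    for region in measure.regionprops(labels):
        if region.area < 50:  # specks cannot be the disk
            continue
        perim = region.perimeter
        if perim <= 0:
            continue
        circularity = 4.0 * math.pi * region.area / (perim * perim)
        # crofton perimeter of a rasterized disk slightly undershoots; cap at 1
        circularity = min(circularity, 1.0)
        radius = math.sqrt(region.area / math.pi)
        cr, cc = region.centroid
        rr, cc_grid = np.ogrid[: red.shape[0], : red.shape[1]]
        inside = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius**2
        n_inside = int(inside.sum())
        red_frac = float((red & inside).sum() / n_inside) if n_inside else 0.0
        if circularity >= CIRCULARITY_MIN and red_frac >= RED_FRACTION_MIN:
            scored.append((circularity * red_frac, radius, (cr, cc), red_frac))
    if not scored:
        raise CalibrationError("calibration disk not found")
    scored.sort(key=lambda t: -t[0])
    if len(scored) > 1 and scored[0][0] - scored[1][0] < AMBIGUITY_MARGIN:
        cands = ", ".join(
            f"(center={c[2][0]:.0f},{c[2][1]:.0f} r={c[1]:.1f}px score={c[0]:.3f})"
            for c in scored[:4]
        )
        raise CalibrationError(f"ambiguous calibration disk candidates: {cands}")
    _, radius, center, _ = scored[0]
    return ScaleCalibration(
        mm_per_px=ref_diameter_mm / (2.0 * radius),
        disk_center=center,
        disk_radius_px=radius,
        ref_diameter_mm=ref_diameter_mm,
    )


def px_to_mm(length_px: float, cal: ScaleCalibration) -> float:
    """Convert a pixel length to millimetres (linear in ``length_px``)."""
    if length_px < 0:
        raise DomainError(f"length_px must be >= 0, got {length_px}")
    return float(length_px) * cal.mm_per_px
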