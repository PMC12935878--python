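"""Grain length and width via ROI segmentation and minimum-area rectangles.

A detection box localizes a grain but does not measure it: boxes are
axis-aligned while grains lie at arbitrary angles, and occlusion can
clip a box. Each high-confidence grain is therefore re-segmented inside
a padded region of interest, small particles are filtered out, and the
minimum-area enclosing rectangle of the grain mask gives length (long
side) and width (short side), converted to millimetres.

Rectangles are computed on pixel-corner polygons — each foreground pixel
contributes its four unit-square corners — so an n-pixel-long bar
measures n, not n-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from shapely import MultiPoint
from skimage import filters, measure, segmentation
from skimage.feature import peak_local_max

from .calibration import RasterImage, ScaleCalibration, px_to_mm
from .detection import GrainDetection
from .errors import DomainError, SegmentationError
from .preprocess import to_grayscale

__all__ = [
    "MinAreaRect",
    "GrainShape",
    "MorphometryConfig",
    "extract_grain_mask",
    "min_area_rect",
    "measure_grain",
    "summarize_grain_dims",
    "grain_shapes_frame",
]


@dataclass(frozen=True)
class MinAreaRect:
    center: tuple[float, float]  # (row, col)
    long_side_px: float
    short_side_px: float
    angle_deg: float  # orientation of the long side, in (-90, 90]


@dataclass(frozen=True)
class GrainShape:
    detection: GrainDetection
    rect: MinAreaRect
    length_mm: float
    width_mm: float
    aspect_ratio: float
    touches_border: bool = False


@dataclass
class MorphometryConfig:
    pad_px: int = 4
    min_particle_px: int = 30
    conf_threshold: float = 0.8


def extract_grain_mask(
    img: RasterImage, det: GrainDetection, cfg: MorphometryConfig | None = None
) -> tuple[np.ndarray, tuple[int, int]]:
    """Segment the grain inside its padded ROI.

    Otsu threshold on the ROI grayscale; components below
    ``min_particle_px`` are dropped; of the survivors the one whose
    centroid is nearest the ROI centre is the grain; holes are filled.
    Returns ``(roi_mask, (roi_r0, roi_c0))`` — the offset locates the ROI
    in image coordinates. Raises :class:`SegmentationError` when nothing
    survives ("grain segmentation failed").
    """
    cfg = cfg or MorphometryConfig()
    h, w = img.shape
    r0, c0, r1, c1 = det.box
    r0, c0 = max(r0 - cfg.pad_px, 0), max(c0 - cfg.pad_px, 0)
    r1, c1 = min(r1 + cfg.pad_px, h), min(c1 + cfg.pad_px, w)
    roi = to_grayscale(img)[r0:r1, c0:c1]
    if np.ptp(roi) < 0.1:  # sensor noise alone spans ~0.05; a grain spans ~0.4
        raise SegmentationError("grain segmentation failed (flat ROI)")
    mask = roi > filters.threshold_otsu(roi)
    # particle filtering: neighbouring grains intrude into the padded ROI
    # and would merge with the target; split the thresholded mask at its
    # brightness cores and keep only the particle owning the ROI centre
    smooth = ndi.gaussian_filter(roi, 1.2)
    peaks = peak_local_max(smooth, min_distance=4, labels=mask, exclude_border=False)
    if len(peaks) > 1:
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = segmentation.watershed(-smooth, markers, mask=mask)
    else:
        labels = measure.label(mask, connectivity=2)
    center = np.array([(r1 - r0) / 2.0, (c1 - c0) / 2.0])
    best_label, best_dist = 0, np.inf
    for region in measure.regionprops(labels):
        if region.area < cfg.min_particle_px:
            continue
        d = float(np.linalg.norm(np.asarray(region.centroid) - center))
        if d < best_dist:
            best_label, best_dist = region.label, d
    if best_label == 0:
        raise SegmentationError("grain segmentation failed (no component)")
    grain = ndi.binary_fill_holes(labels == best_label)
    return grain, (r0, c0)


def min_area_rect(mask: np.ndarray) -> MinAreaRect:
    """Minimum-area enclosing rectangle of a boolean mask's pixel corners.

    Exact via convex hull + rotating calipers (shapely's
    ``minimum_rotated_rectangle``). Degenerate inputs — fewer than 3
    pixels or a collinear set — raise :class:`DomainError`.
    """
    rows, cols = np.nonzero(mask)
    if rows.size < 3:
        raise DomainError("min_area_rect needs >= 3 foreground pixels")
    # pixel-corner point cloud: 4 unit-square corners per pixel
    pts = np.empty((rows.size * 4, 2), dtype=float)
    for i, (dr, dc) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        pts[i * rows.size : (i + 1) * rows.size, 0] = rows + dr
        pts[i * rows.size : (i + 1) * rows.size, 1] = cols + dc
    rect = MultiPoint(pts).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        raise DomainError("degenerate (collinear) pixel set")
    corners = np.asarray(rect.exterior.coords[:4])
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    s1, s2 = float(np.linalg.norm(e1)), float(np.linalg.norm(e2))
    if s1 >= s2:
        long_side, short_side, long_vec = s1, s2, e1
    else:
        long_side, short_side, long_vec = s2, s1, e2
    # angle of the long side against the column (x) axis, mapped to (-90, 90]
    ang = math.degrees(math.atan2(long_vec[0], long_vec[1]))
    ang = (ang + 90.0) % 180.0 - 90.0
    if ang == -90.0:
        ang = 90.0
    center = tuple(np.mean(corners, axis=0))
    return MinAreaRect(
        center=(float(center[0]), float(center[1])),
        long_side_px=long_side,
        short_side_px=short_side,
        angle_deg=ang,
    )


def measure_grain(
    img: RasterImage,
    det: GrainDetection,
    cal: ScaleCalibration,
    cfg: MorphometryConfig | None = None,
) -> GrainShape:
    """Mask -> minimum rectangle -> physical length and width."""
    cfg = cfg or MorphometryConfig()
    grain, (r0, c0) = extract_grain_mask(img, det, cfg)
    rect = min_area_rect(grain)
    rect = MinAreaRect(
        center=(rect.center[0] + r0, rect.center[1] + c0),
        long_side_px=rect.long_side_px,
        short_side_px=rect.short_side_px,
        angle_deg=rect.angle_deg,
    )
    length_mm = px_to_mm(rect.long_side_px, cal)
    width_mm = px_to_mm(rect.short_side_px, cal)
    h, w = img.shape
    br0, bc0, br1, bc1 = det.box
    touches = (
        br0 - cfg.pad_px <= 0 or bc0 - cfg.pad_px <= 0 or br1 + cfg.pad_px >= h or bc1 + cfg.pad_px >= w
    )
    return GrainShape(
        detection=det,
        rect=rect,
        length_mm=length_mm,
        width_mm=width_mm,
        aspect_ratio=length_mm / width_mm,
        touches_border=touches,
    )


def summarize_grain_dims(shapes: list[GrainShape], n_skipped: int = 0) -> dict:
    """Per-panicle summary statistics of the measured grains."""
    out: dict = {"n_measured": len(shapes), "n_skipped": n_skipped}
    if not shapes:
        return out
    for key, vals in (
        ("length_mm", [s.length_mm for s in shapes]),
        ("width_mm", [s.width_mm for s in shapes]),
        ("aspect_ratio", [s.aspect_ratio for s in shapes]),
    ):
        arr = np.asarray(vals)
        out[f"mean_{key}"] = float(arr.mean())
        out[f"median_{key}"] = float(np.median(arr))
        out[f"sd_{key}"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return out


def grain_shapes_frame(image_id: str, shapes: list[GrainShape]):
    """Per-grain measurement table, one row per measured grain."""
    import pandas as pd

    rows = [
        {
            "image_id": image_id,
            "grain_id": i,
            "confidence": s.detection.confidence,
            "length_mm": s.length_mm,
            "width_mm": s.width_mm,
            "aspect_ratio": s.aspect_ratio,
            "angle_deg": s.rect.angle_deg,
            "flag_border": s.touches_border,
        }
        for i, s in enumerate(shapes)
    ]
    columns = [
        "image_id",
        "grain_id",
        "confidence",
        "length_mm",
        "width_mm",
        "aspect_ratio",
        "angle_deg",
        "flag_border",
    ]
    return pd.DataFrame(rows, columns=columns)
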