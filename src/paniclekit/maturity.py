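"""Maturity staging from grain colour via a Hunter-type yellowness index.

As rice ripens the grains shift green -> yellow -> brown. Each grain's
mean sRGB colour is linearized (gamma expansion), converted to CIE XYZ
(sRGB/D65 primaries), then to Hunter-type opponent coordinates
(L lightness, a red-green, b yellow-blue), and condensed into a
yellowness index

    YI = (128 L + 100 a + 30 b) / 100.

The panicle's mean YI over its grains maps to a maturity stage:

    YI < 50          milk
    50 <= YI < 75    dough (wax-ripe)
    75 <= YI <= 100  full maturity
    YI > 100         over-ripe

Two Hunter variants are provided. ``hunter_standard`` (default) uses
L = 10 sqrt(Y) with XYZ on the 0-100 scale, the classical Hunter
lightness, under which the staging bands above are reachable by real
grain colours. ``verbatim`` uses L = 10 Y, kept for audits of the
alternative published form; on the 0-100 XYZ scale it inflates YI far
beyond the bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .calibration import RasterImage
from .errors import ConfigError, DomainError

__all__ = [
    "MaturityStage",
    "HunterLab",
    "YellownessResult",
    "MaturityConfig",
    "mean_grain_rgb",
    "srgb_to_linear",
    "linear_to_xyz",
    "xyz_to_hunter",
    "yellowness_index",
    "classify_maturity",
    "panicle_maturity",
]

#: sRGB -> XYZ matrix (D65), rows X, Y, Z.
SRGB_TO_XYZ = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)


class MaturityStage(str, Enum):
    MILK = "milk"
    DOUGH = "dough"  # a.k.a. wax-ripe
    FULL_MATURITY = "full_maturity"
    OVER_RIPE = "over_ripe"


#: Synonym used in some agronomic sources for the dough stage.
WAX_RIPE = MaturityStage.DOUGH


@dataclass(frozen=True)
class HunterLab:
    L: float
    a: float
    b: float
    variant: str = "hunter_standard"


@dataclass(frozen=True)
class YellownessResult:
    per_grain_yi: list[float]
    mean_yi: float
    stage: MaturityStage
    hist_counts: list[int]
    hist_edges: list[float]


@dataclass
class MaturityConfig:
    variant: str = "hunter_standard"  # or "verbatim"
    xyz_scale: str = "hundred"  # or "unit"
    bins: int = 20


def mean_grain_rgb(img: RasterImage, grain_mask: np.ndarray) -> tuple[float, float, float]:
    """Channel-wise mean colour over the mask, on [0, 255]."""
    if not grain_mask.any():
        raise DomainError("empty grain mask")
    px = img.pixels[grain_mask]
    m = px.mean(axis=0)
    return float(m[0]), float(m[1]), float(m[2])


def srgb_to_linear(R: float, G: float, B: float) -> tuple[float, float, float]:
    """Gamma-expand 8-bit sRGB channels to linear [0, 1] values."""

    def lin(v: float) -> float:
        if not 0.0 <= v <= 255.0:
            raise DomainError(f"channel value {v} outside [0, 255]")
        v /= 255.0
        return ((v + 0.055) / 1.055) ** 2.4 if v > 0.04045 else v / 12.92

    return lin(R), lin(G), lin(B)


def linear_to_xyz(
    lin: tuple[float, float, float], scale: str = "hundred"
) -> tuple[float, float, float]:
    """Linear RGB -> CIE XYZ; ``hundred`` puts the white point at Y = 100."""
    xyz = SRGB_TO_XYZ @ np.asarray(lin, dtype=float)
    if scale == "hundred":
        xyz = xyz * 100.0
    elif scale != "unit":
        raise ConfigError(f"unknown XYZ scale {scale!r}")
    return float(xyz[0]), float(xyz[1]), float(xyz[2])


def xyz_to_hunter(
    xyz: tuple[float, float, float], variant: str = "hunter_standard"
) -> HunterLab:
    """XYZ -> Hunter-type Lab.

    Both variants share a = 175 (X - Y)/Y and b = 70 (Y - Z)/Y; they
    differ in lightness: ``hunter_standard`` L = 10 sqrt(Y) (XYZ on the
    0-100 scale), ``verbatim`` L = 10 Y. Y = 0 maps to (0, 0, 0).
    """
    if variant not in ("hunter_standard", "verbatim"):
        raise ConfigError(f"unknown Hunter variant {variant!r}")
    X, Y, Z = xyz
    if Y <= 0:
        return HunterLab(0.0, 0.0, 0.0, variant)
    a = 175.0 * (X - Y) / Y
    b = 70.0 * (Y - Z) / Y
    L = 10.0 * math.sqrt(Y) if variant == "hunter_standard" else 10.0 * Y
    return HunterLab(L, a, b, variant)


def yellowness_index(lab: HunterLab) -> float:
    """YI = (128 L + 100 a + 30 b) / 100, linear in all three coordinates."""
    return (128.0 * lab.L + 100.0 * lab.a + 30.0 * lab.b) / 100.0


def classify_maturity(mean_yi: float) -> MaturityStage:
    """Map a mean yellowness index to a maturity stage.

    Bands are lower-closed/upper-open, except YI = 100 stays in full
    maturity because over-ripe is strictly above 100.
    """
    if not math.isfinite(mean_yi):
        raise DomainError(f"mean YI must be finite, got {mean_yi}")
    if mean_yi < 50.0:
        return MaturityStage.MILK
    if mean_yi < 75.0:
        return MaturityStage.DOUGH
    if mean_yi <= 100.0:
        return MaturityStage.FULL_MATURITY
    return MaturityStage.OVER_RIPE


def rgb_to_yi(R: float, G: float, B: float, cfg: MaturityConfig | None = None) -> float:
    """Convenience: full colour chain from 8-bit sRGB means to YI."""
    cfg = cfg or MaturityConfig()
    lin = srgb_to_linear(R, G, B)
    xyz = linear_to_xyz(lin, cfg.xyz_scale)
    return yellowness_index(xyz_to_hunter(xyz, cfg.variant))


def save_yi_histogram(result: YellownessResult, path, title: str = "Grain yellowness") -> None:
    """Write a PNG histogram of per-grain yellowness with the stage bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(
        result.hist_edges[:-1],
        result.hist_counts,
        width=[b - a for a, b in zip(result.hist_edges[:-1], result.hist_edges[1:])],
        align="edge",
        color="#d4a017",
        edgecolor="black",
        linewidth=0.3,
    )
    for bound in (50, 75, 100):
        ax.axvline(bound, color="gray", linestyle=":", linewidth=0.8)
    ax.axvline(result.mean_yi, color="red", linewidth=1.2, label=f"mean YI = {result.mean_yi:.1f}")
    ax.set_xlabel("yellowness index")
    ax.set_ylabel("grains")
    ax.set_title(f"{title} — {result.stage.value}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def panicle_maturity(
    img: RasterImage,
    grain_masks: list[np.ndarray],
    cfg: MaturityConfig | None = None,
) -> YellownessResult:
    """Per-grain YI, mean, stage, and a YI histogram for the panicle.

    ``grain_masks`` are full-image boolean masks (one per grain), as
    produced by placing each ROI grain mask at its offset.
    """
    cfg = cfg or MaturityConfig()
    if not grain_masks:
        raise DomainError("no grains for maturity analysis")
    yis = [rgb_to_yi(*mean_grain_rgb(img, m), cfg) for m in grain_masks]
    mean_yi = float(np.mean(yis))
    counts, edges = np.histogram(yis, bins=cfg.bins)
    return YellownessResult(
        per_grain_yi=yis,
        mean_yi=mean_yi,
        stage=classify_maturity(mean_yi),
        hist_counts=counts.tolist(),
        hist_edges=edges.tolist(),
    )
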