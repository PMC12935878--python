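"""Two-stage occlusion-corrected grain counting.

Grains on a panicle occlude one another, so a detector systematically
undercounts — the denser the panicle, the worse. The correction is a
per-density-class linear regression from the visible (detected) count X
to the estimated total count Y:

    class 1 (loose):  Y = 1.136 X + 12.67
    class 2 (normal): Y = 1.555 X - 6.191
    class 3 (dense):  Y = 1.821 X - 29.2

The default coefficients ship with the package; ``fit_correction``
refits them by ordinary least squares from (detected, true) pairs, e.g.
produced on a locally imaged calibration set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy import stats
from skimage import morphology

from .calibration import RasterImage
from .detection import DetectionSet
from .errors import ConfigError, DomainError, ModelError

__all__ = [
    "DensityClass",
    "CountCorrectionModel",
    "CountResult",
    "DensityConfig",
    "classify_density",
    "correct_count",
    "fit_correction",
    "count_grains",
]


class DensityClass(IntEnum):
    """Panicle morphology class encoding occlusion severity."""

    LOOSE = 1
    NORMAL = 2
    DENSE = 3


#: Per-class (slope, intercept) of the shipped correction regressions.
DEFAULT_COEFFICIENTS: dict[int, tuple[float, float]] = {
    1: (1.136, 12.67),
    2: (1.555, -6.191),
    3: (1.821, -29.2),
}


@dataclass(frozen=True)
class CountCorrectionModel:
    coefficients: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    r_squared: dict[int, float] | None = None

    def __post_init__(self) -> None:
        for cls, (slope, _) in self.coefficients.items():
            if slope <= 0:
                raise ModelError(f"class {cls}: slope must be > 0, got {slope}")

    def params(self, cls: DensityClass | int) -> tuple[float, float]:
        try:
            return self.coefficients[int(cls)]
        except KeyError:
            raise ModelError(f"density class {int(cls)} missing from correction model")

    def to_json(self) -> str:
        return json.dumps(
            {str(c): {"slope": s, "intercept": b} for c, (s, b) in self.coefficients.items()}
        )

    @classmethod
    def from_json(cls, text: str) -> "CountCorrectionModel":
        d = json.loads(text)
        return cls({int(k): (v["slope"], v["intercept"]) for k, v in d.items()})

    @classmethod
    def load(cls, path: str | Path) -> "CountCorrectionModel":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class CountResult:
    raw_count: int
    density: DensityClass
    corrected_float: float
    corrected_count: int


@dataclass
class DensityConfig:
    """Occupancy thresholds for the heuristic density classifier.

    Occupancy = (sum of detection-box areas) / (panicle convex-hull
    area); overlapping boxes count multiply, so dense panicles exceed 1.
    Thresholds are package defaults calibrated on the bundled synthetic
    generator, not field-derived constants.
    """

    t1: float = 0.50
    t2: float = 0.65
    override: DensityClass | None = None  # injected label wins over the heuristic


def classify_density(
    img: RasterImage,
    mask: np.ndarray,
    dets: DetectionSet,
    cfg: DensityConfig | None = None,
) -> DensityClass:
    """Heuristic occupancy-based density class (1 loose / 2 normal / 3 dense).

    Boundary occupancies are assigned upward: exactly ``t1`` is NORMAL,
    exactly ``t2`` is NORMAL (DENSE requires strictly more).
    """
    cfg = cfg or DensityConfig()
    if cfg.override is not None:
        return DensityClass(cfg.override)
    if cfg.t1 >= cfg.t2:
        raise ConfigError(f"require t1 < t2, got t1={cfg.t1} t2={cfg.t2}")
    if not mask.any():
        raise DomainError("empty panicle mask")
    hull_area = int(morphology.convex_hull_image(mask).sum())
    box_area = sum(d.area for d in dets)
    occupancy = box_area / hull_area
    if occupancy < cfg.t1:
        return DensityClass.LOOSE
    if occupancy > cfg.t2:
        return DensityClass.DENSE
    return DensityClass.NORMAL


def correct_count(
    raw_count: int,
    cls: DensityClass | int,
    model: CountCorrectionModel | None = None,
) -> CountResult:
    """Apply the class-specific linear correction to a visible-grain count.

    ``corrected_float`` keeps the regression output; ``corrected_count``
    rounds half away from zero and clamps at 0 (a count cannot be
    negative, which the dense-class intercept makes possible at tiny X).
    """
    if raw_count < 0:
        raise DomainError(f"raw_count must be >= 0, got {raw_count}")
    model = model or CountCorrectionModel()
    slope, intercept = model.params(cls)
    corrected = slope * raw_count + intercept
    rounded = math.floor(corrected + 0.5) if corrected >= 0 else -math.floor(-corrected + 0.5)
    return CountResult(
        raw_count=int(raw_count),
        density=DensityClass(int(cls)),
        corrected_float=corrected,
        corrected_count=max(0, rounded),
    )


def fit_correction(
    pairs: dict[int, list[tuple[float, float]]],
) -> CountCorrectionModel:
    """Ordinary least-squares refit of the per-class correction lines.

    ``pairs`` maps density class -> list of (detected, true) counts.
    Requires >= 3 pairs per class and non-constant detected counts.
    """
    coeffs: dict[int, tuple[float, float]] = {}
    r2: dict[int, float] = {}
    for cls, data in pairs.items():
        if len(data) < 3:
            raise ModelError(f"class {cls}: need >= 3 pairs, got {len(data)}")
        x = np.asarray([p[0] for p in data], dtype=float)
        y = np.asarray([p[1] for p in data], dtype=float)
        if np.ptp(x) == 0:
            raise ModelError(f"class {cls}: detected counts are constant, cannot fit")
        res = stats.linregress(x, y)
        coeffs[int(cls)] = (float(res.slope), float(res.intercept))
        r2[int(cls)] = float(res.rvalue**2)
    return CountCorrectionModel(coefficients=coeffs, r_squared=r2)


def count_grains(
    img: RasterImage,
    mask: np.ndarray,
    dets: DetectionSet,
    model: CountCorrectionModel | None = None,
    cfg: DensityConfig | None = None,
) -> CountResult:
    """Classify density, then correct the raw visible count."""
    cls = classify_density(img, mask, dets, cfg)
    return correct_count(len(dets), cls, model)
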