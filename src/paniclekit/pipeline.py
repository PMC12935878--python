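"""End-to-end per-image and batch analysis.

``analyze_image`` chains calibration -> segmentation -> length ->
detection -> counting -> morphometry -> maturity. Each stage degrades
gracefully: a failure records a reason code and nulls for that stage's
fields without aborting the rest of the image or the batch.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    RasterImage,
    ScaleCalibration,
    detect_reference_disk,
    load_image,
)
from .counting import CountCorrectionModel, DensityClass, DensityConfig, count_grains
from .detection import (
    DetectionSet,
    DetectorConfig,
    detect_grains_reference,
    filter_by_confidence,
    load_detections,
)
from .errors import PanicleKitError
from .maturity import MaturityConfig, panicle_maturity
from .morphometry import MorphometryConfig, extract_grain_mask, measure_grain, summarize_grain_dims
from .preprocess import SegmentConfig, segment_panicle
from .skeleton import SkeletonConfig, measure_panicle_length

__all__ = ["AnalysisConfig", "REPORT_COLUMNS", "analyze_image", "analyze_batch"]

log = logging.getLogger("paniclekit")

REPORT_COLUMNS = [
    "image_id",
    "mm_per_px",
    "panicle_length_mm",
    "neck_row",
    "neck_col",
    "path_px",
    "density",
    "raw_count",
    "corrected_count",
    "n_grains_measured",
    "n_grains_skipped",
    "mean_length_mm",
    "mean_width_mm",
    "mean_aspect_ratio",
    "mean_yi",
    "maturity_stage",
    "reasons",
]


@dataclass
class AnalysisConfig:
    ref_diameter_mm: float = 30.0
    mm_per_px: float | None = None  # overrides disk detection entirely
    density_override: int | None = None  # 1/2/3 to bypass the heuristic
    conf_threshold: float = 0.8
    detections_path: str | None = None  # external detections bypass the reference detector
    count_model_path: str | None = None
    maturity_variant: str = "hunter_standard"
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    maturity: MaturityConfig = field(default_factory=MaturityConfig)

    def __post_init__(self) -> None:
        self.skeleton.segment = self.segment
        self.morphometry.conf_threshold = self.conf_threshold
        self.maturity.variant = self.maturity_variant

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                for k, v in value.items():
                    setattr(current, k, v)
            else:
                setattr(cfg, key, value)
        cfg.__post_init__()
        return cfg

    def digest(self) -> str:
        blob = json.dumps(
            {f.name: repr(getattr(self, f.name)) for f in dataclasses.fields(self)},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def analyze_image(
    path: str | Path | RasterImage,
    config: AnalysisConfig | None = None,
    model: CountCorrectionModel | None = None,
) -> dict:
    """Analyze one image; returns a report row (missing stages -> None).

    Stage failures are recorded as ``reason_code`` strings in the
    ``reasons`` field instead of raising, so a batch never aborts on one
    bad image.
    """
    cfg = config or AnalysisConfig()
    reasons: list[str] = []
    report: dict = {c: None for c in REPORT_COLUMNS}

    if isinstance(path, RasterImage):
        img = path
        report["image_id"] = Path(img.path).stem
    else:
        try:
            img = load_image(path)
        except PanicleKitError as exc:
            report["image_id"] = Path(str(path)).stem
            report["reasons"] = f"unreadable_image:{exc}"
            return report
        report["image_id"] = Path(str(path)).stem

    cal: ScaleCalibration | None = None
    if cfg.mm_per_px is not None:
        cal = ScaleCalibration.from_mm_per_px(cfg.mm_per_px)
    else:
        try:
            cal = detect_reference_disk(img, cfg.ref_diameter_mm)
        except PanicleKitError:
            reasons.append("no_calibration")
    if cal is not None:
        report["mm_per_px"] = cal.mm_per_px

    mask = None
    try:
        mask = segment_panicle(img, cal, cfg.segment)
    except PanicleKitError:
        reasons.append("no_panicle")

    if mask is not None and cal is not None:
        try:
            t0 = time.perf_counter()
            length = measure_panicle_length(img, cal, cfg.skeleton, mask=mask)
            log.info("length stage: %.2fs", time.perf_counter() - t0)
            report["panicle_length_mm"] = length.length_mm
            report["neck_row"], report["neck_col"] = length.neck
            report["path_px"] = length.length_px
        except PanicleKitError:
            reasons.append("length_failed")

    dets: DetectionSet | None = None
    if cfg.detections_path:
        try:
            dets, _ = load_detections(cfg.detections_path, img.shape)
        except PanicleKitError:
            reasons.append("bad_detections_file")
    elif mask is not None:
        dets = detect_grains_reference(img, mask, cfg.detector)

    if dets is not None and mask is not None:
        try:
            count_model = (
                model
                if model is not None
                else (
                    CountCorrectionModel.load(cfg.count_model_path)
                    if cfg.count_model_path
                    else CountCorrectionModel()
                )
            )
            density_cfg = DensityConfig(
                override=DensityClass(cfg.density_override) if cfg.density_override else None
            )
            count = count_grains(img, mask, dets, count_model, density_cfg)
            report["density"] = int(count.density)
            report["raw_count"] = count.raw_count
            report["corrected_count"] = count.corrected_count
        except PanicleKitError:
            reasons.append("count_failed")

    if dets is not None:
        confident = filter_by_confidence(dets, cfg.conf_threshold)
        shapes, grain_masks, skipped = [], [], 0
        for det in confident:
            try:
                if cal is not None:
                    shapes.append(measure_grain(img, det, cal, cfg.morphometry))
                roi_mask, (r0, c0) = extract_grain_mask(img, det, cfg.morphometry)
                full = np.zeros(img.shape, dtype=bool)
                full[r0 : r0 + roi_mask.shape[0], c0 : c0 + roi_mask.shape[1]] = roi_mask
                grain_masks.append(full)
            except PanicleKitError:
                skipped += 1
        if cal is None:
            reasons.append("dims_skipped_no_calibration")
        if shapes:
            summary = summarize_grain_dims(shapes, n_skipped=skipped)
            report["n_grains_measured"] = summary["n_measured"]
            report["n_grains_skipped"] = summary["n_skipped"]
            report["mean_length_mm"] = summary.get("mean_length_mm")
            report["mean_width_mm"] = summary.get("mean_width_mm")
            report["mean_aspect_ratio"] = summary.get("mean_aspect_ratio")
        if grain_masks:
            try:
                ymat = panicle_maturity(img, grain_masks, cfg.maturity)
                report["mean_yi"] = ymat.mean_yi
                report["maturity_stage"] = ymat.stage.value
            except PanicleKitError:
                reasons.append("maturity_failed")
        else:
            reasons.append("no_confident_grains")

    report["reasons"] = ";".join(reasons) if reasons else ""
    return report


IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def analyze_batch(
    target: str | Path,
    out_csv: str | Path,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Analyze a directory (or single file) and write CSV + JSON reports."""
    cfg = config or AnalysisConfig()
    target = Path(target)
    if target.is_dir():
        files = sorted(p for p in target.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    else:
        files = [target]
    if not files:
        raise PanicleKitError(f"no images found in {target}")
    rows = [analyze_image(p, cfg) for p in files]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS).sort_values("image_id").reset_index(drop=True)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False)
    meta = {
        "version": __version__,
        "config_digest": cfg.digest(),
        "n_images": len(files),
        "n_errors": int(df["reasons"].str.contains("unreadable_image").sum()),
    }
    out_csv.with_suffix(".json").write_text(
        json.dumps({"metadata": meta, "reports": df.to_dict(orient="records")}, indent=1)
    )
    return df
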