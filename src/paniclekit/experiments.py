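"""Recovery studies on synthetic scenes: the package's validation harness.

These experiments generate seeded synthetic panicles with known ground
truth, run the full measurement pipeline on them, and score how well
each trait is recovered:

* panicle length — MAPE between measured and true axis length;
* grain count — per-density-class regressions refitted on a training
  split, corrected counts scored by R² on the held-out split;
* grain dimensions — mean absolute length/width error (px) on a
  scattered-grain field where every grain is fully visible;
* maturity — stage agreement between predicted and generating stage;
* density — classifier accuracy against the generating class.

Counting regressions are fitted and applied under the generating density
label so the regression experiment is not confounded by classifier
mistakes; the classifier is scored separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import detect_reference_disk
from .counting import classify_density, correct_count, fit_correction
from .detection import detect_grains_reference, filter_by_confidence
from .maturity import panicle_maturity
from .metrics import PairedSeries, box_iou, r_squared
from .morphometry import extract_grain_mask, min_area_rect
from .preprocess import segment_panicle
from .skeleton import measure_panicle_length
from .synthetic import dataset_specs, generate_grain_field, generate_panicle

__all__ = ["RecoveryResult", "run_recovery_study", "run_morphometry_study"]


@dataclass
class RecoveryResult:
    """Scores of one end-to-end synthetic recovery run."""

    n_images: int
    length_mape_pct: float
    count_r2_heldout: float
    count_slopes: dict[int, float]
    stage_agreement_pct: float
    density_accuracy_pct: float
    length_errors_pct: list[float] = field(default_factory=list)


def run_recovery_study(
    n_per_class: int = 50,
    master_seed: int = 7,
    conf_threshold: float = 0.8,
) -> RecoveryResult:
    """Generate ``3 * n_per_class`` panicles and score trait recovery."""
    n = 3 * n_per_class
    specs = dataset_specs(n, master_seed=master_seed)
    len_err = []
    count_pairs: dict[int, list[tuple[float, float]]] = {1: [], 2: [], 3: []}
    stage_hits: list[bool] = []
    density_hits: list[bool] = []

    for spec in specs:
        img, gt = generate_panicle(spec)
        cal = detect_reference_disk(img)
        mask = segment_panicle(img, cal)

        res = measure_panicle_length(img, cal, mask=mask)
        len_err.append((res.length_mm - gt.axis_length_mm) / gt.axis_length_mm * 100.0)

        dets = detect_grains_reference(img, mask)
        density_hits.append(classify_density(img, mask, dets) == gt.density)
        count_pairs[int(gt.density)].append((len(dets), gt.total_grains))

        grain_masks = []
        for det in filter_by_confidence(dets, conf_threshold):
            try:
                roi_mask, (r0, c0) = extract_grain_mask(img, det)
            except Exception:
                continue
            full = np.zeros(img.shape, dtype=bool)
            full[r0 : r0 + roi_mask.shape[0], c0 : c0 + roi_mask.shape[1]] = roi_mask
            grain_masks.append(full)
        if grain_masks:
            stage_hits.append(panicle_maturity(img, grain_masks).stage == gt.stage)
        else:
            stage_hits.append(False)

    train = {c: v[::2] for c, v in count_pairs.items()}
    test = {c: v[1::2] for c, v in count_pairs.items()}
    model = fit_correction(train)
    actual, predicted = [], []
    for c, pairs in test.items():
        for det_count, total in pairs:
            actual.append(float(total))
            predicted.append(correct_count(int(det_count), c, model).corrected_float)
    series = PairedSeries(np.asarray(actual), np.asarray(predicted))

    abs_err = np.abs(np.asarray(len_err))
    return RecoveryResult(
        n_images=n,
        length_mape_pct=float(abs_err.mean()),
        count_r2_heldout=r_squared(series),
        count_slopes={c: model.coefficients[c][0] for c in sorted(model.coefficients)},
        stage_agreement_pct=100.0 * float(np.mean(stage_hits)),
        density_accuracy_pct=100.0 * float(np.mean(density_hits)),
        length_errors_pct=len_err,
    )


def run_morphometry_study(
    n_grains: int = 200,
    master_seed: int = 7,
    grains_per_field: int = 40,
    mm_per_px: float = 0.3,
    conf_threshold: float = 0.8,
) -> dict:
    """Measure scattered fully-visible grains and score dimension recovery.

    Returns mean absolute errors in px and mm for grain length and
    width, plus the measured-grain count. Detections are matched to
    ground truth at IoU >= 0.5.
    """
    from .calibration import ScaleCalibration

    cal = ScaleCalibration.from_mm_per_px(mm_per_px)
    len_err_px, wid_err_px = [], []
    n_fields = int(np.ceil(n_grains / grains_per_field))
    for i in range(n_fields):
        img, gts = generate_grain_field(
            grains_per_field, seed=master_seed * 1000 + i, mm_per_px=mm_per_px
        )
        mask = img.pixels.max(axis=2) > 60
        dets = filter_by_confidence(detect_grains_reference(img, mask), conf_threshold)
        for det in dets:
            best = max(gts, key=lambda g: box_iou(det.box, g.box))
            if box_iou(det.box, best.box) < 0.5:
                continue
            try:
                roi_mask, _off = extract_grain_mask(img, det)
                rect = min_area_rect(roi_mask)
            except Exception:
                continue
            len_err_px.append(rect.long_side_px - 2.0 * best.semi_axes_px[0])
            wid_err_px.append(rect.short_side_px - 2.0 * best.semi_axes_px[1])
            if len(len_err_px) >= n_grains:
                break
        if len(len_err_px) >= n_grains:
            break
    le = np.abs(np.asarray(len_err_px))
    we = np.abs(np.asarray(wid_err_px))
    return {
        "n_measured": int(le.size),
        "length_mean_abs_err_px": float(le.mean()),
        "width_mean_abs_err_px": float(we.mean()),
        "length_mean_abs_err_mm": float(le.mean() * mm_per_px),
        "width_mean_abs_err_mm": float(we.mean() * mm_per_px),
    }
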