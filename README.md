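# paniclekit

Image-based phenotyping of rice panicles. From a single RGB photograph of
a panicle on a dark background — with a red circular reference disk of
known diameter in the scene — `paniclekit` measures four yield- and
quality-related traits:

1. **Panicle length** (mm): the panicle mask is thinned to a skeleton
   modelled as an 8-connected weighted graph (orthogonal steps weigh 1,
   diagonal steps √2). The *neck* — the lowest branching point of the
   skeleton — is located, the stalk below it is pruned, and panicle
   length is the longest simple path from the neck, found exactly by
   depth-first search with branch-and-bound pruning, then converted to
   millimetres with the disk-derived scale.
2. **Grain count**: grains visible to a detector under-represent the true
   total because grains occlude each other. The panicle is first
   classified into a density class *c* ∈ {1 loose, 2 normal, 3 dense}
   and the visible count X is corrected by a class-specific linear
   regression Y<sub>c</sub> = a<sub>c</sub>·X + b<sub>c</sub>, with shipped
   coefficients (1.136, 12.67), (1.555, −6.191), (1.821, −29.2). The
   coefficients can be refitted from (detected, true) pairs by ordinary
   least squares.
3. **Grain length and width** (mm): each high-confidence detection is
   re-segmented inside a padded region of interest, neighbouring
   particles are filtered out, and the minimum-area enclosing rectangle
   of the grain mask gives length (long side) and width (short side).
4. **Maturity stage**: each grain's mean sRGB colour is linearized,
   converted to CIE XYZ and then to Hunter-type opponent coordinates
   (L, a, b), and condensed into a yellowness index
   YI = (128 L + 100 a + 30 b)/100. The panicle's mean YI maps to a
   stage: milk (< 50), dough/wax-ripe [50, 75), full maturity [75, 100],
   over-ripe (> 100).

Grain detections enter through a pluggable interface: a classical
reference detector (brightness-core watershed) is bundled so the whole
pipeline runs without any trained model, and detections exported from an
external detector (e.g. a YOLO variant) can be loaded from CSV/JSON
instead.

A deterministic synthetic-scene generator (`paniclekit.synthetic`)
renders curved panicles with calibration disk, density-controlled grain
crowding, stage-dependent grain colours, and exact ground truth, so
every stage of the pipeline is testable end to end without any image
downloads.

## Worked example

```bash
# render 6 synthetic panicles with ground truth
paniclekit synth scenes --n 6 --seed 1

# run the full trait pipeline
paniclekit analyze scenes --out report.csv
```

which prints `analyzed 6 image(s), 0 unreadable -> report.csv`. The CSV
holds one row per image; the first row of that run (transposed) is

```
image_id           panicle_0000
mm_per_px          0.3006
panicle_length_mm  166.58
density            1
raw_count          68
corrected_count    90
mean_length_mm     8.45
mean_width_mm      4.33
mean_aspect_ratio  2.00
mean_yi            19.20
maturity_stage     milk
```

Reading: the disk was measured at 0.3006 mm/px (the generator's true
scale is 0.3); the skeleton path from neck to tip is 166.6 mm; the
detector saw 68 grains and the loose-class (density 1) correction
estimates 90 in total; the 61 confidently measured grains average
8.5 × 4.3 mm; and the mean yellowness of 19.2 places the panicle in the
milk stage — which is indeed the stage this scene was generated at.

The same machinery is available as a library:

```python
from paniclekit import (PanicleSpec, generate_panicle,
                        detect_reference_disk, segment_panicle,
                        measure_panicle_length)

img, gt = generate_panicle(PanicleSpec(seed=1))
cal = detect_reference_disk(img)          # mm-per-px from the red disk
mask = segment_panicle(img, cal)
res = measure_panicle_length(img, cal, mask=mask)
```

Other subcommands: `paniclekit fit-count-model pairs.csv` refits the
count-correction regressions, `paniclekit eval pred.csv truth.csv`
reports R²/MAE/MAPE/RMSE between two trait CSVs.

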