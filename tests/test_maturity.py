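"""Colour chain: sRGB -> linear -> XYZ -> Hunter-type Lab -> yellowness."""

import numpy as np
import pytest

from paniclekit.calibration import RasterImage
from paniclekit.errors import ConfigError, DomainError
from paniclekit.maturity import (
    HunterLab,
    MaturityConfig,
    MaturityStage,
    classify_maturity,
    linear_to_xyz,
    mean_grain_rgb,
    panicle_maturity,
    rgb_to_yi,
    srgb_to_linear,
    xyz_to_hunter,
    yellowness_index,
)


class TestLinearization:
    @pytest.mark.parametrize(
        "value,expected,tol",
        [(255, 1.0, 1e-12), (0, 0.0, 1e-12), (128, 0.21586, 5e-5)],
    )
    def test_reference_values(self, value, expected, tol):
        r, g, b = srgb_to_linear(value, value, value)
        assert r == pytest.approx(expected, abs=tol)
        assert r == g == b

    def test_below_knee_is_linear(self):
        v = 0.04045 * 255 * 0.5
        r, _, _ = srgb_to_linear(v, 0, 0)
        assert r == pytest.approx((v / 255) / 12.92, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            srgb_to_linear(256, 0, 0)


class TestXYZ:
    def test_white_point(self):
        xyz = linear_to_xyz((1.0, 1.0, 1.0), "hundred")
        assert xyz[0] == pytest.approx(95.05, abs=0.01)
        assert xyz[1] == pytest.approx(100.0, abs=0.01)
        assert xyz[2] == pytest.approx(108.90, abs=0.01)

    def test_black(self):
        assert linear_to_xyz((0, 0, 0), "hundred") == (0, 0, 0)

    def test_pure_red_primary(self):
        xyz = linear_to_xyz((1.0, 0.0, 0.0), "hundred")
        assert xyz == pytest.approx((41.24, 21.26, 1.93), abs=0.01)

    def test_unit_scale_is_hundredth(self):
        u = linear_to_xyz((0.3, 0.5, 0.2), "unit")
        h = linear_to_xyz((0.3, 0.5, 0.2), "hundred")
        assert np.allclose(np.array(h), 100 * np.array(u))


class TestHunter:
    def test_achromatic_axis_zero_chroma(self):
        for variant in ("hunter_standard", "verbatim"):
            lab = xyz_to_hunter((50.0, 50.0, 50.0), variant)
            assert lab.a == 0.0 and lab.b == 0.0

    def test_white_hunter_standard(self):
        lab = xyz_to_hunter((95.05, 100.0, 108.90), "hunter_standard")
        assert lab.L == pytest.approx(100.0, abs=1e-9)
        assert lab.a == pytest.approx(-8.66, abs=0.01)
        assert lab.b == pytest.approx(-6.23, abs=0.01)

    def test_white_verbatim_lightness(self):
        lab = xyz_to_hunter((95.05, 100.0, 108.90), "verbatim")
        assert lab.L == pytest.approx(1000.0, abs=1e-9)
        assert lab.a == pytest.approx(-8.66, abs=0.01)

    def test_zero_y_convention(self):
        lab = xyz_to_hunter((10.0, 0.0, 5.0))
        assert (lab.L, lab.a, lab.b) == (0.0, 0.0, 0.0)

    def test_unknown_variant(self):
        with pytest.raises(ConfigError):
            xyz_to_hunter((1, 1, 1), "cielab")

    def test_gray_axis_chroma_independent_of_level(self):
        labs = [
            xyz_to_hunter(linear_to_xyz(srgb_to_linear(v, v, v), "hundred"))
            for v in (32, 128, 224)
        ]
        assert max(l.a for l in labs) - min(l.a for l in labs) < 1e-9
        assert max(l.b for l in labs) - min(l.b for l in labs) < 1e-9


class TestYellownessIndex:
    @pytest.mark.parametrize(
        "lab,expected",
        [
            (HunterLab(100, 0, 0), 128.0),
            (HunterLab(0, 0, 0), 0.0),
            (HunterLab(50, -40, 38), 35.4),
        ],
    )
    def test_formula(self, lab, expected):
        assert yellowness_index(lab) == pytest.approx(expected, abs=1e-9)

    def test_linear_in_lab(self):
        rng = np.random.default_rng(2)
        l1 = HunterLab(*rng.uniform(-50, 100, 3))
        l2 = HunterLab(*rng.uniform(-50, 100, 3))
        for alpha in (0.0, 0.3, 1.0):
            mix = HunterLab(
                alpha * l1.L + (1 - alpha) * l2.L,
                alpha * l1.a + (1 - alpha) * l2.a,
                alpha * l1.b + (1 - alpha) * l2.b,
            )
            expected = alpha * yellowness_index(l1) + (1 - alpha) * yellowness_index(l2)
            assert yellowness_index(mix) == pytest.approx(expected, abs=1e-9)

    def test_partial_derivatives(self):
        base = HunterLab(40.0, 5.0, 10.0)
        eps = 1e-6
        dL = (yellowness_index(HunterLab(40 + eps, 5, 10)) - yellowness_index(base)) / eps
        da = (yellowness_index(HunterLab(40, 5 + eps, 10)) - yellowness_index(base)) / eps
        db = (yellowness_index(HunterLab(40, 5, 10 + eps)) - yellowness_index(base)) / eps
        assert dL == pytest.approx(1.28, abs=1e-6)
        assert da == pytest.approx(1.00, abs=1e-6)
        assert db == pytest.approx(0.30, abs=1e-6)


class TestStaging:
    @pytest.mark.parametrize(
        "yi,stage",
        [
            (49.9, MaturityStage.MILK),
            (50.0, MaturityStage.DOUGH),
            (74.99, MaturityStage.DOUGH),
            (75.0, MaturityStage.FULL_MATURITY),
            (100.0, MaturityStage.FULL_MATURITY),
            (100.01, MaturityStage.OVER_RIPE),
        ],
    )
    def test_band_boundaries(self, yi, stage):
        assert classify_maturity(yi) == stage

    def test_monotone_step_function(self):
        order = [MaturityStage.MILK, MaturityStage.DOUGH, MaturityStage.FULL_MATURITY, MaturityStage.OVER_RIPE]
        stages = [order.index(classify_maturity(yi)) for yi in np.linspace(0, 150, 301)]
        assert all(b >= a for a, b in zip(stages, stages[1:]))

    def test_nonfinite_rejected(self):
        with pytest.raises(DomainError):
            classify_maturity(float("nan"))


class TestMeanGrainRGB:
    def test_uniform_patch(self):
        img = RasterImage(np.full((40, 40, 3), (200, 180, 60), dtype=np.uint8), "u")
        mask = np.ones((40, 40), bool)
        assert mean_grain_rgb(img, mask) == (200.0, 180.0, 60.0)

    def test_half_black_half_white(self):
        px = np.zeros((40, 40, 3), dtype=np.uint8)
        px[20:] = 255
        img = RasterImage(px, "bw")
        assert mean_grain_rgb(img, np.ones((40, 40), bool)) == (127.5, 127.5, 127.5)

    def test_matches_numpy_mean(self):
        rng = np.random.default_rng(6)
        px = rng.integers(0, 255, (50, 50, 3), dtype=np.uint8)
        mask = rng.random((50, 50)) > 0.5
        img = RasterImage(px, "r")
        got = mean_grain_rgb(img, mask)
        for k in range(3):
            assert got[k] == pytest.approx(px[:, :, k][mask].mean(), abs=1e-9)

    def test_empty_mask_rejected(self):
        img = RasterImage(np.zeros((40, 40, 3), dtype=np.uint8), "e")
        with pytest.raises(DomainError):
            mean_grain_rgb(img, np.zeros((40, 40), bool))


class TestPanicleMaturity:
    def test_uniform_grains_mean_equals_single_color(self):
        color = (200, 175, 65)
        img = RasterImage(np.full((60, 60, 3), color, dtype=np.uint8), "u")
        masks = [np.zeros((60, 60), bool) for _ in range(3)]
        masks[0][5:15, 5:15] = True
        masks[1][20:30, 20:30] = True
        masks[2][40:50, 40:50] = True
        res = panicle_maturity(img, masks)
        assert res.mean_yi == pytest.approx(rgb_to_yi(*map(float, color)), abs=1e-9)

    def test_zero_grains_rejected(self):
        img = RasterImage(np.zeros((40, 40, 3), dtype=np.uint8), "z")
        with pytest.raises(DomainError, match="no grains"):
            panicle_maturity(img, [])

    def test_brighter_yellower_grains_raise_mean(self):
        px = np.full((60, 60, 3), (150, 140, 70), dtype=np.uint8)
        px[30:, :] = (220, 190, 50)  # brighter and yellower
        img = RasterImage(px, "mix")
        dull = np.zeros((60, 60), bool)
        dull[5:15, 5:15] = True
        bright = np.zeros((60, 60), bool)
        bright[40:50, 5:15] = True
        only_dull = panicle_maturity(img, [dull])
        mixed = panicle_maturity(img, [dull, bright])
        assert mixed.mean_yi >= only_dull.mean_yi

    def test_histogram_totals_match_grain_count(self):
        rng = np.random.default_rng(10)
        px = rng.integers(40, 250, (80, 80, 3), dtype=np.uint8)
        img = RasterImage(px, "h")
        masks = []
        for i in range(6):
            m = np.zeros((80, 80), bool)
            m[i * 12 : i * 12 + 8, 10:30] = True
            masks.append(m)
        res = panicle_maturity(img, masks, MaturityConfig(bins=5))
        assert sum(res.hist_counts) == 6
        assert len(res.hist_edges) == 6
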