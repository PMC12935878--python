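"""Synthetic panicle image generator with exact ground truth.

Emulates the acquisition protocol the pipeline targets: a single curved
panicle photographed on a dark background next to a red circular
calibration disk of known physical diameter. The rachis is a quadratic
Bezier stroke with a stalk below the neck; grains are rotated filled
ellipses scattered in a tapering tube around the rachis, coloured by
maturity stage (green -> yellow-green -> yellow -> deep golden) with
per-grain jitter. Grain crowding (the tube radius and grain count) is
controlled by the density class, emulating the loose/normal/dense
occlusion regimes.

Occlusion is modelled by *omission*: a ``hidden_fraction`` of grains is
counted in the ground-truth total but never rendered, so the
visible-to-total ratio the count-correction regression must recover is
exact and controllable. Default hidden fractions (loose 0.10, normal
0.30, dense 0.45) give inverse-visibility slopes 1.11 / 1.43 / 1.82,
ordered like the shipped correction slopes.

Every image is generated from a single pseudo-random stream derived
from the seed, so identical specs give byte-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import draw

from .calibration import RasterImage, ScaleCalibration
from .counting import DensityClass
from .errors import DomainError
from .maturity import MaturityStage

__all__ = [
    "PanicleSpec",
    "GrainGT",
    "GroundTruth",
    "generate_panicle",
    "generate_dataset",
    "generate_grain_field",
    "dataset_specs",
    "gt_calibration",
    "quad_bezier_arc_length",
    "STAGE_PALETTES",
    "DENSITY_DEFAULTS",
]

#: Mean grain colour per maturity stage (8-bit sRGB), chosen so the mean
#: yellowness index lands mid-band for each stage.
STAGE_PALETTES: dict[MaturityStage, tuple[int, int, int]] = {
    MaturityStage.MILK: (100, 150, 80),
    MaturityStage.DOUGH: (165, 162, 90),
    MaturityStage.FULL_MATURITY: (200, 175, 65),
    MaturityStage.OVER_RIPE: (250, 210, 25),
}

#: Radial shading amplitude: grain rim is darker than the core by this
#: fraction, giving each grain a brightness core like real glossy grains.
GRAIN_SHADING = 0.10

RACHIS_COLOR = (105, 95, 55)  # duller than any grain palette
BACKGROUND_LEVEL = 12
DISK_COLOR = (200, 30, 30)

#: Per-density-class defaults: (grains per 100 px of axis, tube_radius_px,
#: hidden_fraction, curvature, taper, min_separation). min_separation is the
#: rejection threshold on the normalized centre distance between rendered
#: grains — smaller values permit heavier visible overlap, so the classes
#: look progressively more crowded while each visible grain keeps an
#: exposed core.
DENSITY_DEFAULTS: dict[DensityClass, tuple[float, float, float, float, float, float]] = {
    DensityClass.LOOSE: (14.0, 42.0, 0.10, 0.10, 0.6, 0.50),
    DensityClass.NORMAL: (22.5, 30.0, 0.30, 0.08, 0.6, 0.40),
    DensityClass.DENSE: (33.0, 20.0, 0.45, 0.05, 0.5, 0.30),
}

#: Panicle length range sampled when the spec leaves axis_length_mm open.
AXIS_LENGTH_RANGE_MM = (115.0, 190.0)


@dataclass
class PanicleSpec:
    """Parameters of one synthetic panicle scene."""

    seed: int = 0
    image_size: tuple[int, int] = (800, 640)
    disk_radius_px: float = 50.0
    ref_diameter_mm: float = 30.0
    axis_length_mm: float | None = None  # None -> sampled from AXIS_LENGTH_RANGE_MM
    axis_curvature: float | None = None  # Bezier bow as a chord fraction; None -> density default
    n_grains: int | None = None  # None -> density default
    density: DensityClass = DensityClass.LOOSE
    hidden_fraction: float | None = None  # None -> density default
    grain_len_mm: float = 9.0
    grain_wid_mm: float = 3.6
    grain_sd_mm: float = 0.5
    stage: MaturityStage = MaturityStage.FULL_MATURITY
    stalk_px: float = 60.0
    noise_sd: float = 2.0

    @property
    def mm_per_px(self) -> float:
        return self.ref_diameter_mm / (2.0 * self.disk_radius_px)

    def resolved(self, rng: np.random.Generator | None = None) -> "PanicleSpec":
        per_100px, _tube, hidden, curv, _taper, _sep = DENSITY_DEFAULTS[self.density]
        out = replace(self)
        if out.axis_length_mm is None:
            lo, hi = AXIS_LENGTH_RANGE_MM
            out.axis_length_mm = float(rng.uniform(lo, hi)) if rng is not None else (lo + hi) / 2
        if out.n_grains is None:
            # grain total scales with panicle length at a class-specific
            # linear density (longer panicles bear more grains), so the
            # count-correction regression sees genuine variation in X
            axis_px = out.axis_length_mm / out.mm_per_px
            jitter = float(rng.uniform(0.92, 1.08)) if rng is not None else 1.0
            out.n_grains = max(int(round(per_100px * axis_px / 100.0 * jitter)), 1)
        if out.hidden_fraction is None:
            out.hidden_fraction = hidden
        if out.axis_curvature is None:
            out.axis_curvature = curv
        if out.n_grains < 1:
            raise DomainError("n_grains must be >= 1")
        if not 0.0 <= out.hidden_fraction < 1.0:
            raise DomainError("hidden_fraction must be in [0, 1)")
        return out


@dataclass(frozen=True)
class GrainGT:
    center: tuple[float, float]
    semi_axes_px: tuple[float, float]  # (a, b), a >= b
    angle_deg: float
    box: tuple[int, int, int, int]
    color: tuple[int, int, int]
    visible: bool


@dataclass(frozen=True)
class GroundTruth:
    axis_length_mm: float
    mm_per_px: float
    density: DensityClass
    stage: MaturityStage
    grains: list[GrainGT]
    disk_center: tuple[float, float]
    disk_radius_px: float
    bezier: tuple[np.ndarray, np.ndarray, np.ndarray]  # control points P0, P1, P2

    @property
    def total_grains(self) -> int:
        return len(self.grains)

    @property
    def visible_grains(self) -> list[GrainGT]:
        return [g for g in self.grains if g.visible]


def quad_bezier_arc_length(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Closed-form arc length of a quadratic Bezier curve.

    With u = P1-P0, d = (P2-P1)-(P1-P0), the speed is
    ``2*sqrt(|d|^2 t^2 + 2 (u.d) t + |u|^2)`` whose antiderivative is the
    standard sqrt-quadratic integral. Degenerate control layouts
    (collinear / coincident points) fall back to exact special cases.
    """
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    u = p1 - p0
    d = (p2 - p1) - u
    a = float(d @ d)
    b = 2.0 * float(u @ d)
    c = float(u @ u)
    if a < 1e-12:  # P1 is the midpoint: the curve is the straight segment
        return 2.0 * math.sqrt(c)

    def antideriv(t: float) -> float:
        q = math.sqrt(max(a * t * t + b * t + c, 0.0))
        sa = math.sqrt(a)
        term1 = (2.0 * a * t + b) * q / (4.0 * a)
        disc = 4.0 * a * c - b * b
        arg = 2.0 * a * t + b + 2.0 * sa * q
        if disc <= 1e-12 or arg <= 0:  # collinear controls: |linear| integrand
            return term1
        return term1 + disc / (8.0 * a * sa) * math.log(arg)

    return 2.0 * (antideriv(1.0) - antideriv(0.0))


def _bezier_point(p0, p1, p2, t):
    t = np.asarray(t, dtype=float)[..., None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _bezier_tangent(p0, p1, p2, t):
    t = np.asarray(t, dtype=float)[..., None]
    return 2 * (1 - t) * (p1 - p0) + 2 * t * (p2 - p1)


def _build_axis(spec: PanicleSpec, rng: np.random.Generator):
    """Place the rachis Bezier so its arc length hits the requested mm."""
    h, w = spec.image_size
    target_px = spec.axis_length_mm / spec.mm_per_px
    p0 = np.array([h - 1.4 * spec.stalk_px - 12.0, 0.62 * w])
    direction = np.array([-1.0, rng.uniform(-0.25, -0.05)])  # up, leaning left
    direction /= np.linalg.norm(direction)
    perp = np.array([-direction[1], direction[0]])
    bow = spec.axis_curvature * rng.choice([-1.0, 1.0])
    # unit-chord shape, then scale the chord so the arc length matches
    q0 = np.zeros(2)
    q2 = direction.copy()
    q1 = 0.5 * direction + bow * perp
    unit_len = quad_bezier_arc_length(q0, q1, q2)
    chord = target_px / unit_len
    p1 = p0 + q1 * chord
    p2 = p0 + q2 * chord
    if p2[0] < 30 or not (30 < p2[1] < w - 30):
        # steep/bowed draw would leave the frame; fall back to a gentler layout
        q2 = np.array([-1.0, -0.12])
        q2 /= np.linalg.norm(q2)
        q1 = 0.5 * q2 + 0.08 * np.array([-q2[1], q2[0]])
        chord = target_px / quad_bezier_arc_length(np.zeros(2), q1, q2)
        p1, p2 = p0 + q1 * chord, p0 + q2 * chord
    return p0, p1, p2


def _stamp_stroke(canvas, pts, radius, color):
    for r, c in pts:
        rr, cc = draw.disk((r, c), radius, shape=canvas.shape[:2])
        canvas[rr, cc] = color


def _ellipse_bbox(center, a, b, theta_rad, shape):
    """Axis-aligned half-open box of a rotated ellipse, clipped to the image."""
    hr = math.sqrt((a * math.sin(theta_rad)) ** 2 + (b * math.cos(theta_rad)) ** 2)
    hc = math.sqrt((a * math.cos(theta_rad)) ** 2 + (b * math.sin(theta_rad)) ** 2)
    r0 = max(int(math.floor(center[0] - hr)), 0)
    c0 = max(int(math.floor(center[1] - hc)), 0)
    r1 = min(int(math.ceil(center[0] + hr)) + 1, shape[0])
    c1 = min(int(math.ceil(center[1] + hc)) + 1, shape[1])
    return r0, c0, r1, c1


def generate_panicle(spec: PanicleSpec) -> tuple[RasterImage, GroundTruth]:
    """Render one panicle scene and its exact ground truth."""
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    spec = spec.resolved(rng)
    canvas = np.zeros((h, w, 3), dtype=np.float64)
    canvas[:] = BACKGROUND_LEVEL

    p0, p1, p2 = _build_axis(spec, rng)
    arc_px = quad_bezier_arc_length(p0, p1, p2)
    axis_length_mm = arc_px * spec.mm_per_px

    # arc-length parametrization for uniform grain placement
    ts = np.linspace(0.0, 1.0, 400)
    pts = _bezier_point(p0, p1, p2, ts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    cum /= cum[-1]

    def at_arc(s):
        return np.interp(s, cum, ts)

    # rachis + stalk strokes
    stalk_end = p0 + np.array([spec.stalk_px, rng.uniform(-8, 8)])
    stalk_pts = np.linspace(p0, stalk_end, int(spec.stalk_px))
    _stamp_stroke(canvas, stalk_pts, 3.0, RACHIS_COLOR)
    _stamp_stroke(canvas, pts, 3.0, RACHIS_COLOR)

    disk_center = (70.0, 65.0)
    disk_clear = spec.disk_radius_px + 30.0  # keep-out radius for grains

    _, tube_radius, _, _, taper_strength, min_sep = DENSITY_DEFAULTS[spec.density]
    palette = np.array(STAGE_PALETTES[spec.stage], dtype=float)
    n = spec.n_grains
    n_hidden = int(round(spec.hidden_fraction * n))

    a_mean = spec.grain_len_mm / 2.0 / spec.mm_per_px
    b_mean = spec.grain_wid_mm / 2.0 / spec.mm_per_px
    sd_px = spec.grain_sd_mm / 2.0 / spec.mm_per_px

    # short branch strokes from the rachis toward where grains cluster
    for _ in range(max(n // 8, 4)):
        t = float(at_arc(rng.uniform(0.05, 0.98)))
        base = _bezier_point(p0, p1, p2, t)
        tan = _bezier_tangent(p0, p1, p2, t)
        tan /= np.linalg.norm(tan)
        perp = np.array([-tan[1], tan[0]]) * rng.choice([-1.0, 1.0])
        length = rng.uniform(0.4, 1.0) * tube_radius
        bpts = np.linspace(base, base + perp * length + tan * length * 0.6, max(int(length), 2))
        _stamp_stroke(canvas, bpts, 1.2, RACHIS_COLOR)

    grains: list[GrainGT] = []

    # basal anchor branches: two short primary branches just above the neck,
    # each bearing grains held clear of the main tube. Real panicles branch
    # at the neck; these guarantee a skeleton junction there, which is what
    # neck detection keys on.
    anchor_sites: list[tuple[np.ndarray, float]] = []
    for s_a, side in ((0.025, 1.0), (0.055, -1.0)):
        t = float(at_arc(s_a))
        base = _bezier_point(p0, p1, p2, t)
        tan = _bezier_tangent(p0, p1, p2, t)
        tan /= np.linalg.norm(tan)
        perp = np.array([-tan[1], tan[0]]) * side
        out_dir = 0.75 * perp + 0.3 * tan
        out_dir /= np.linalg.norm(out_dir)
        blen = max(1.6 * tube_radius, 22.0)
        bpts = np.linspace(base, base + out_dir * blen, max(int(blen), 2))
        _stamp_stroke(canvas, bpts, 1.2, RACHIS_COLOR)
        ang = math.atan2(out_dir[0], out_dir[1])
        anchor_sites.append((base + out_dir * blen, ang))
        anchor_sites.append((base + out_dir * (0.65 * blen) + perp * 3.0, ang))

    order = np.argsort(rng.uniform(size=n))  # deterministic placement order
    # hidden grains are drawn from the non-anchor positions: the basal
    # anchors must render so the neck junction exists
    n_anchored = min(len(anchor_sites), n)
    candidates = order[n_anchored:]
    n_hidden = min(n_hidden, candidates.size)
    hidden_idx = set(rng.choice(candidates, size=n_hidden, replace=False).tolist())
    # rendered-grain bookkeeping for overlap rejection: centres and sizes
    placed_centers: list[np.ndarray] = []
    placed_axes: list[tuple[float, float]] = []
    n_forced = 0

    def _separation(center: np.ndarray, a: float, b: float, theta: float) -> float:
        """Smallest normalized centre distance to any rendered grain."""
        if not placed_centers:
            return np.inf
        delta = np.asarray(placed_centers) - center
        sn, cs = math.sin(theta), math.cos(theta)
        along = delta[:, 0] * sn + delta[:, 1] * cs
        across = delta[:, 0] * cs - delta[:, 1] * sn
        axes = np.asarray(placed_axes)
        return float(
            np.sqrt((along / (a + axes[:, 0])) ** 2 + (across / (b + axes[:, 1])) ** 2).min()
        )

    for i in order.tolist():
        a = max(float(rng.normal(a_mean, sd_px)), 4.0)
        b = max(float(rng.normal(b_mean, sd_px * 0.5)), 2.0)
        if a < b:
            a, b = b, a
        visible = i not in hidden_idx
        anchor = anchor_sites.pop() if anchor_sites else None
        if anchor is not None:
            center, tangent_ang = anchor
            theta = tangent_ang + rng.normal(0.0, 0.15)
        else:
            best: tuple[float, np.ndarray, float] | None = None
            for _attempt in range(60):
                s = rng.uniform(0.08, 1.0)
                t = float(at_arc(s))
                base = _bezier_point(p0, p1, p2, t)
                tan = _bezier_tangent(p0, p1, p2, t)
                tan /= np.linalg.norm(tan)
                perp = np.array([-tan[1], tan[0]])
                taper = 1.0 - taper_strength * s  # the panicle narrows toward the tip
                offset = rng.uniform(-1.0, 1.0) * tube_radius * taper
                shift = rng.uniform(-4, 4)
                if s > 0.95:
                    # tip grains align with the axis and extend past the curve
                    # end, like the terminal spikelet of a real panicle
                    offset *= 0.25
                    shift = rng.uniform(0.0, 6.0)
                cand = base + perp * offset + tan * shift
                if not (8 < cand[0] < h - 8 and 8 < cand[1] < w - 8):
                    continue
                if np.hypot(cand[0] - disk_center[0], cand[1] - disk_center[1]) < disk_clear:
                    continue
                cand_theta = math.atan2(tan[0], tan[1]) + rng.normal(
                    0.0, 0.12 if s > 0.95 else 0.3
                )
                sep = _separation(cand, a, b, cand_theta) if visible else np.inf
                if best is None or sep > best[0]:
                    best = (sep, cand, cand_theta)
                if sep >= min_sep:
                    break
            if best is None:
                raise DomainError(
                    "cannot place all grains without entering the calibration-disk "
                    "region; use a larger image or fewer grains"
                )
            sep, center, theta = best
            if visible and sep < min_sep:
                n_forced += 1
        if visible:
            placed_centers.append(np.asarray(center, dtype=float))
            placed_axes.append((a, b))
        color = tuple(
            int(np.clip(palette[k] + rng.uniform(-8, 8), 0, 255)) for k in range(3)
        )
        if visible:
            rr, cc = draw.ellipse(
                center[0], center[1], b, a, shape=(h, w), rotation=-theta
            )
            # radial shading: bright core, rim darker by GRAIN_SHADING.
            # The area-mean of the elliptical radius^2 is 1/2, so the mean
            # rendered colour is (1 - GRAIN_SHADING/2) x the base colour.
            dy = rr - center[0]
            dx = cc - center[1]
            along = dy * math.sin(theta) + dx * math.cos(theta)
            across = dy * math.cos(theta) - dx * math.sin(theta)
            rho2 = np.clip((along / a) ** 2 + (across / b) ** 2, 0.0, 1.0)
            shade = (1.0 - GRAIN_SHADING * rho2)[:, None]
            canvas[rr, cc] = np.asarray(color, dtype=float) * shade
        box = _ellipse_bbox(center, a, b, theta, (h, w))
        grains.append(
            GrainGT(
                center=(float(center[0]), float(center[1])),
                semi_axes_px=(a, b),
                angle_deg=math.degrees(theta) % 180.0,
                box=box,
                color=color,
                visible=visible,
            )
        )

    rr, cc = draw.disk(disk_center, spec.disk_radius_px, shape=(h, w))
    canvas[rr, cc] = DISK_COLOR

    noise = rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    img8 = np.clip(canvas + noise, 0, 255).astype(np.uint8)
    image = RasterImage(pixels=img8, path=f"synthetic-{spec.seed}")
    gt = GroundTruth(
        axis_length_mm=axis_length_mm,
        mm_per_px=spec.mm_per_px,
        density=spec.density,
        stage=spec.stage,
        grains=grains,
        disk_center=disk_center,
        disk_radius_px=spec.disk_radius_px,
        bezier=(p0, p1, p2),
    )
    return image, gt


def generate_grain_field(
    n: int,
    seed: int = 0,
    image_size: tuple[int, int] = (520, 520),
    mm_per_px: float = 0.3,
    stage: MaturityStage = MaturityStage.FULL_MATURITY,
    grain_len_mm: float = 9.0,
    grain_wid_mm: float = 3.6,
    grain_sd_mm: float = 0.5,
    noise_sd: float = 2.0,
) -> tuple[RasterImage, list[GrainGT]]:
    """Render ``n`` non-overlapping shaded grains scattered on a dark field.

    A threshing-table scene: grains laid out individually, no panicle, no
    mutual occlusion. This isolates the morphometry and colour chains
    from occlusion effects — every ground-truth grain is fully visible.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    h, w = image_size
    rng = np.random.default_rng(seed)
    canvas = np.full((h, w, 3), float(BACKGROUND_LEVEL))
    palette = np.array(STAGE_PALETTES[stage], dtype=float)
    a_mean, b_mean = grain_len_mm / 2.0 / mm_per_px, grain_wid_mm / 2.0 / mm_per_px
    sd_px = grain_sd_mm / 2.0 / mm_per_px
    margin = a_mean + 6
    placed: list[np.ndarray] = []
    grains: list[GrainGT] = []
    clearance = 2.4 * a_mean
    for _ in range(n):
        center = None
        for _attempt in range(200):
            cand = np.array(
                [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
            )
            if all(np.linalg.norm(cand - p) >= clearance for p in placed):
                center = cand
                break
        if center is None:
            raise DomainError(f"cannot place {n} grains in a {h}x{w} field")
        placed.append(center)
        a = max(float(rng.normal(a_mean, sd_px)), 4.0)
        b = max(float(rng.normal(b_mean, sd_px * 0.5)), 2.0)
        if a < b:
            a, b = b, a
        theta = rng.uniform(0, math.pi)
        color = tuple(int(np.clip(palette[k] + rng.uniform(-8, 8), 0, 255)) for k in range(3))
        rr, cc = draw.ellipse(center[0], center[1], b, a, shape=(h, w), rotation=-theta)
        dy, dx = rr - center[0], cc - center[1]
        along = dy * math.sin(theta) + dx * math.cos(theta)
        across = dy * math.cos(theta) - dx * math.sin(theta)
        rho2 = np.clip((along / a) ** 2 + (across / b) ** 2, 0.0, 1.0)
        canvas[rr, cc] = np.asarray(color, dtype=float) * (1.0 - GRAIN_SHADING * rho2)[:, None]
        grains.append(
            GrainGT(
                center=(float(center[0]), float(center[1])),
                semi_axes_px=(a, b),
                angle_deg=math.degrees(theta) % 180.0,
                box=_ellipse_bbox(center, a, b, theta, (h, w)),
                color=color,
                visible=True,
            )
        )
    noise = rng.normal(0.0, noise_sd, size=canvas.shape)
    img8 = np.clip(canvas + noise, 0, 255).astype(np.uint8)
    return RasterImage(pixels=img8, path=f"grainfield-{seed}"), grains


def gt_calibration(gt: GroundTruth, ref_diameter_mm: float = 30.0) -> ScaleCalibration:
    """The exact calibration implied by the rendered disk (for oracles)."""
    return ScaleCalibration(
        mm_per_px=gt.mm_per_px,
        disk_center=gt.disk_center,
        disk_radius_px=gt.disk_radius_px,
        ref_diameter_mm=ref_diameter_mm,
    )


def _image_seed(master_seed: int, index: int) -> int:
    """Stable per-image seed below 2**31 derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def dataset_specs(
    n: int,
    master_seed: int = 0,
    template: PanicleSpec | None = None,
    densities: list[DensityClass] | None = None,
    stages: list[MaturityStage] | None = None,
) -> list[PanicleSpec]:
    """Per-image specs cycling through densities and stages deterministically."""
    if n < 1:
        raise DomainError("n must be >= 1")
    template = template or PanicleSpec()
    densities = densities or list(DensityClass)
    stages = stages or list(MaturityStage)
    specs = []
    for i in range(n):
        specs.append(
            replace(
                template,
                seed=_image_seed(master_seed, i),
                density=densities[i % len(densities)],
                stage=stages[(i // len(densities)) % len(stages)],
                n_grains=None,
                hidden_fraction=None,
            )
        )
    return specs


def generate_dataset(
    n: int,
    out_dir: str | Path,
    master_seed: int = 0,
    template: PanicleSpec | None = None,
) -> pd.DataFrame:
    """Write ``n`` PNGs plus panicle- and grain-level ground-truth CSVs.

    Returns the panicle-level frame. Columns follow the detection CSV
    schema for grains (``image_id,r0,c0,r1,c1,confidence,label``) plus
    ``len_px,wid_px,visible``.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panicle_rows, grain_rows = [], []
    for i, spec in enumerate(dataset_specs(n, master_seed, template)):
        img, gt = generate_panicle(spec)
        image_id = f"panicle_{i:04d}"
        iio.imwrite(out_dir / f"{image_id}.png", img.pixels)
        panicle_rows.append(
            {
                "image_id": image_id,
                "density": int(gt.density),
                "stage": gt.stage.value,
                "axis_length_mm": gt.axis_length_mm,
                "total_grains": gt.total_grains,
                "visible_grains": len(gt.visible_grains),
                "mm_per_px": gt.mm_per_px,
            }
        )
        for g in gt.grains:
            grain_rows.append(
                {
                    "image_id": image_id,
                    "r0": g.box[0],
                    "c0": g.box[1],
                    "r1": g.box[2],
                    "c1": g.box[3],
                    "confidence": 1.0,
                    "label": "grain",
                    "len_px": 2 * g.semi_axes_px[0],
                    "wid_px": 2 * g.semi_axes_px[1],
                    "visible": g.visible,
                }
            )
    panicles = pd.DataFrame(panicle_rows)
    panicles.to_csv(out_dir / "ground_truth_panicles.csv", index=False)
    pd.DataFrame(grain_rows).to_csv(out_dir / "ground_truth_grains.csv", index=False)
    return panicles
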