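"""Synthetic whole-body DXA phantoms with analytic ground truth.

Real supine whole-body scans of adolescents are access-controlled, so every
pipeline stage is exercised on parameterised phantoms instead: a body
silhouette assembled from an elliptical head, a tapering torso, a wide
pelvis band and two leg capsules, with the spine rendered as a bright
Gaussian-profile band along a controllable midline.

The midline lateral offset is a piecewise-cosine bump (single C curve) or a
pair of opposite-signed bumps (double S curve) in normalised spine position,
chosen so the column offset and its derivative are available in closed form.
The bump amplitude is solved numerically so that the tangent-angle range of
the midline equals the requested curve angle exactly, which makes the ground
truth analytic: re-measuring the noiseless midline recovers the injected
angle.

Positioning perturbations (whole-body tilt, lateral offset, leg-length
asymmetry) and Poisson-plus-Gaussian imaging noise emulate repeat-scan
repositioning; the same rigid transform is applied to the image, the truth
masks and the truth midline so they stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .curvature import GRADE_NONE, grade_curve
from .errors import InvalidInputError, SizingError
from .preprocessing import DxaImage, save_image

PATTERNS = ("straight", "single_C", "double_S")

# ---- silhouette geometry, as fractions of image height (H) / width (W) ----------
_HEAD_CY, _HEAD_RY, _HEAD_RX = 0.08, 0.06, 0.085  # RX is a fraction of W
_NECK_TOP, _NECK_BOT, _NECK_HW = 0.13, 0.16, 0.06
_SHOULDER_ROW, _PELVIS_TOP, _PELVIS_BOT = 0.16, 0.52, 0.62
_TORSO_HW_TOP, _TORSO_HW_BOT = 0.22, 0.16
_PELVIS_HW = 0.24
_LEG_BOT, _LEG_CX, _LEG_HW = 0.97, 0.12, 0.065
_SPINE_TOP, _SPINE_BOT = 0.17, 0.56
_SPINE_SIGMA_FRAC = 3.0 / 800.0  # Gaussian cross-section sigma, fraction of H

_BACKGROUND, _SOFT, _SPINE_AMP = 0.02, 0.35, 0.55
_PHOTON_SCALE = 2000.0  # counts per unit intensity for the Poisson component

# a phantom parameter counts as a true positioning error when it exceeds
# these thresholds (chosen so the default positioning score crosses 0.5)
POSITIONING_TILT_DEG = 5.0
POSITIONING_OFFSET_FRAC = 0.075  # of width
POSITIONING_ASYM = 0.1

_MIN_HEIGHT, _MIN_WIDTH = 120, 60


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom scan."""

    image_height_px: int = 800
    image_width_px: int = 300
    curve_angle_deg: float = 0.0
    curve_pattern: str = "straight"
    apex_row_fraction: float = 0.5
    noise_sigma: float = 0.02
    tilt_deg: float = 0.0
    lateral_offset_px: float = 0.0
    leg_asymmetry: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.curve_pattern not in PATTERNS:
            raise InvalidInputError(f"unknown curve_pattern {self.curve_pattern!r}")
        if (self.curve_angle_deg == 0) != (self.curve_pattern == "straight"):
            raise InvalidInputError("curve_angle_deg must be 0 iff curve_pattern is 'straight'")
        if self.curve_angle_deg < 0:
            raise InvalidInputError("curve_angle_deg must be non-negative")
        if not 0.0 < self.apex_row_fraction < 1.0:
            raise InvalidInputError("apex_row_fraction must lie strictly inside (0, 1)")
        if self.curve_pattern == "double_S" and not self.apex_row_fraction < 0.5:
            raise InvalidInputError("double_S needs the first apex in (0, 0.5)")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be non-negative")
        if not 0.0 <= self.leg_asymmetry <= 1.0:
            raise InvalidInputError("leg_asymmetry must lie in [0, 1]")


@dataclass(frozen=True)
class RepositioningJitter:
    """Standard deviations of the re-sampled pose between repeat scans."""

    tilt_sd_deg: float = 2.0
    offset_sd_px: float = 4.0
    asym_sd: float = 0.02

    def __post_init__(self) -> None:
        if min(self.tilt_sd_deg, self.offset_sd_px, self.asym_sd) < 0:
            raise InvalidInputError("jitter magnitudes must be non-negative")


@dataclass
class GroundTruth:
    """Analytic truth attached to a generated phantom."""

    true_midline: np.ndarray  # (n, 2): row, column, in the posed image frame
    true_angle_deg: float
    true_class: str
    true_positioning_error: bool
    masks: dict[str, np.ndarray] = field(default_factory=dict)  # truth label masks


# ----------------------------------------------------------------------------------
# midline shape family
# ----------------------------------------------------------------------------------


def _shape(u: np.ndarray, pattern: str, p: float) -> np.ndarray:
    """Unit-amplitude lateral offset s(u), u in [0, 1]."""
    u = np.asarray(u, dtype=float)
    if pattern == "straight":
        return np.zeros_like(u)
    if pattern == "single_C":
        rising = (1.0 - np.cos(np.pi * u / p)) / 2.0
        falling = (1.0 + np.cos(np.pi * (u - p) / (1.0 - p))) / 2.0
        return np.where(u <= p, rising, falling) - 0.5
    # double_S: opposite-signed bumps meeting at m = 2p with zero slope
    m = 2.0 * p
    bump = lambda v: (1.0 - np.cos(2.0 * np.pi * v)) / 2.0
    first = bump(np.clip(u, 0, m) / m)
    second = -bump((np.clip(u, m, 1) - m) / (1.0 - m))
    return np.where(u <= m, first, second)


def _shape_slope_extrema(pattern: str, p: float) -> tuple[float, float]:
    """(max, min) of ds/du over [0, 1], in closed form."""
    if pattern == "straight":
        return 0.0, 0.0
    if pattern == "single_C":
        return np.pi / (2.0 * p), -np.pi / (2.0 * (1.0 - p))
    m = 2.0 * p
    s = np.pi / min(m, 1.0 - m)
    return s, -s


def solve_amplitude(angle_deg: float, pattern: str, p: float, span_rows: float) -> float:
    """Amplitude (pixels) giving the requested tangent-angle range.

    The tangent-angle range of ``col(r) = a * s((r - r0)/L)`` is
    ``atan(a*smax/L) - atan(a*smin/L)``; this is strictly increasing in
    ``a`` and solved by bisection.
    """
    if angle_deg == 0 or pattern == "straight":
        return 0.0
    smax, smin = _shape_slope_extrema(pattern, p)
    target = np.radians(angle_deg)

    def f(a: float) -> float:
        return np.arctan(a * smax / span_rows) + np.arctan(a * abs(smin) / span_rows) - target

    hi = span_rows * np.tan(min(target, 0.99 * np.pi) / 2.0) / min(smax, abs(smin)) + 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 0.0, hi, xtol=1e-10))


def tangent_range_deg(cols: np.ndarray, rows: np.ndarray) -> float:
    """Analytic tangent-angle range of a sampled midline (degrees)."""
    slope = np.gradient(np.asarray(cols, float), np.asarray(rows, float))
    theta = np.degrees(np.arctan(slope))
    return float(theta.max() - theta.min())


# ----------------------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------------------


def _pose_matrices(h: int, w: int, tilt_deg: float, offset_px: float):
    """Rotation about the image centre plus lateral shift, in (row, col)."""
    phi = np.radians(tilt_deg)
    # positive tilt leans the head end toward larger columns
    rot = np.array([[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]])
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([0.0, offset_px])
    return rot, centre, shift


def _pose_image(img: np.ndarray, tilt_deg: float, offset_px: float, order: int, cval: float) -> np.ndarray:
    if tilt_deg == 0 and offset_px == 0:
        return img
    rot, centre, shift = _pose_matrices(*img.shape, tilt_deg, offset_px)
    inv = rot.T
    offset = centre - inv @ (centre + shift)
    return ndimage.affine_transform(img, inv, offset=offset, order=order, cval=cval, mode="constant")


def _pose_points(points: np.ndarray, shape: tuple[int, int], tilt_deg: float, offset_px: float) -> np.ndarray:
    if tilt_deg == 0 and offset_px == 0:
        return points
    rot, centre, shift = _pose_matrices(shape[0], shape[1], tilt_deg, offset_px)
    return (points - centre) @ rot.T + centre + shift


def _render(spec: PhantomSpec) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """Noiseless, unposed phantom: image, truth masks, intrinsic midline."""
    h, w = spec.image_height_px, spec.image_width_px
    if h < _MIN_HEIGHT or w < _MIN_WIDTH:
        raise SizingError(
            f"canvas {h}x{w} too small for all body structures "
            f"(need >= {_MIN_HEIGHT}x{_MIN_WIDTH})"
        )
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    cx = (w - 1) / 2.0

    head = ((rr - _HEAD_CY * h) / (_HEAD_RY * h)) ** 2 + ((cc - cx) / (_HEAD_RX * w)) ** 2 <= 1.0
    neck = (rr >= _NECK_TOP * h) & (rr < _NECK_BOT * h) & (np.abs(cc - cx) <= _NECK_HW * w)
    t = np.clip((rr - _SHOULDER_ROW * h) / ((_PELVIS_TOP - _SHOULDER_ROW) * h), 0, 1)
    torso_hw = (_TORSO_HW_TOP + (_TORSO_HW_BOT - _TORSO_HW_TOP) * t) * w
    torso = (rr >= _SHOULDER_ROW * h) & (rr < _PELVIS_TOP * h) & (np.abs(cc - cx) <= torso_hw)
    pelvis = (rr >= _PELVIS_TOP * h) & (rr < _PELVIS_BOT * h) & (np.abs(cc - cx) <= _PELVIS_HW * w)

    leg_top = _PELVIS_BOT * h
    full_len = (_LEG_BOT - _PELVIS_BOT) * h
    left_bot = leg_top + full_len * (1.0 - spec.leg_asymmetry)
    left = (rr >= leg_top) & (rr < left_bot) & (np.abs(cc - (cx - _LEG_CX * w)) <= _LEG_HW * w)
    right = (rr >= leg_top) & (rr < leg_top + full_len) & (np.abs(cc - (cx + _LEG_CX * w)) <= _LEG_HW * w)

    body = head | neck | torso | pelvis | left | right
    img = np.full((h, w), _BACKGROUND)
    img[body] = _SOFT

    # spine band along the analytic midline
    r0, r1 = int(round(_SPINE_TOP * h)), int(round(_SPINE_BOT * h))
    rows = np.arange(r0, r1 + 1)
    span = float(rows[-1] - rows[0])
    amp = solve_amplitude(spec.curve_angle_deg, spec.curve_pattern, spec.apex_row_fraction, span)
    u = (rows - rows[0]) / span
    cols_mid = cx + amp * _shape(u, spec.curve_pattern, spec.apex_row_fraction)

    sigma = _SPINE_SIGMA_FRAC * h
    reach = int(np.ceil(4 * sigma))
    col_idx = np.arange(w, dtype=float)
    spine_mask = np.zeros((h, w), dtype=bool)
    half_mask = sigma * np.sqrt(2.0 * np.log(2.0))
    for r, c in zip(rows, cols_mid):
        lo, hi_ = max(0, int(c) - reach), min(w, int(c) + reach + 1)
        img[r, lo:hi_] += _SPINE_AMP * np.exp(-((col_idx[lo:hi_] - c) ** 2) / (2 * sigma**2))
        spine_mask[r, lo:hi_] = np.abs(col_idx[lo:hi_] - c) <= half_mask

    masks = {
        "head": head,
        "spine": spine_mask,
        "pelvis": pelvis & ~spine_mask,
        "left_leg": left,
        "right_leg": right,
    }
    midline = np.column_stack([rows.astype(float), cols_mid])
    return img, masks, midline


def generate_phantom(spec: PhantomSpec) -> tuple[DxaImage, GroundTruth]:
    """Generate one phantom scan and its ground truth.

    Deterministic for a fixed spec (including the seed, which drives only
    the noise).  The truth midline and masks are expressed in the posed
    image frame; ``true_angle_deg`` is the intrinsic (pose-invariant) curve
    angle.
    """
    img, masks, midline = _render(spec)

    img = _pose_image(img, spec.tilt_deg, spec.lateral_offset_px, order=1, cval=_BACKGROUND)
    masks = {
        k: _pose_image(m.astype(np.float32), spec.tilt_deg, spec.lateral_offset_px, order=0, cval=0.0) > 0.5
        for k, m in masks.items()
    }
    midline = _pose_points(midline, img.shape, spec.tilt_deg, spec.lateral_offset_px)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = rng.poisson(np.clip(img, 0, None) * _PHOTON_SCALE) / _PHOTON_SCALE
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, None)

    pos_error = (
        abs(spec.tilt_deg) > POSITIONING_TILT_DEG
        or abs(spec.lateral_offset_px) > POSITIONING_OFFSET_FRAC * spec.image_width_px
        or spec.leg_asymmetry > POSITIONING_ASYM
    )
    gt = GroundTruth(
        true_midline=midline,
        true_angle_deg=float(spec.curve_angle_deg),
        true_class=grade_curve(spec.curve_angle_deg),
        true_positioning_error=bool(pos_error),
        masks=masks,
    )
    image = DxaImage(pixels=img, image_id=f"phantom_{spec.seed:08d}")
    return image, gt


def generate_repeat_pair(
    spec: PhantomSpec, jitter: RepositioningJitter
) -> tuple[DxaImage, DxaImage, GroundTruth]:
    """Two scans of the same spine with re-sampled positioning in between.

    The second scan perturbs tilt, lateral offset and leg asymmetry by
    zero-mean Gaussian draws of the given jitter SDs and uses fresh noise;
    the underlying spine (pattern, angle, apex) is identical.  With zero
    jitter and zero noise the two images are bit-identical.
    """
    rng = np.random.default_rng(np.uint32(spec.seed * 2654435761 % 2**31))
    img1, gt = generate_phantom(spec)
    spec2 = replace(
        spec,
        tilt_deg=spec.tilt_deg + (rng.normal(0, jitter.tilt_sd_deg) if jitter.tilt_sd_deg else 0.0),
        lateral_offset_px=spec.lateral_offset_px
        + (rng.normal(0, jitter.offset_sd_px) if jitter.offset_sd_px else 0.0),
        leg_asymmetry=float(
            np.clip(spec.leg_asymmetry + (rng.normal(0, jitter.asym_sd) if jitter.asym_sd else 0.0), 0, 1)
        ),
        seed=spec.seed + 1_000_003,
    )
    img2, _ = generate_phantom(spec2)
    return img1, img2, gt


# ----------------------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------------------


@dataclass(frozen=True)
class AngleDistributions:
    """Uniform curve-angle ranges (degrees) per ground-truth class.

    Defaults keep the non-scoliotic class clearly below the 6-degree
    boundary and start the major class at 11 degrees, away from the
    mild/major boundary, emulating a screening population rather than a
    boundary stress test.
    """

    none: tuple[float, float] = (0.0, 4.0)
    mild: tuple[float, float] = (6.0, 10.0)
    major: tuple[float, float] = (11.0, 28.0)


def _draw_spec(
    rng: np.random.Generator,
    idx: int,
    scoliotic: bool,
    angles: AngleDistributions,
    mild_fraction: float,
    double_fraction: float,
    positioning_error_rate: float,
    height_px: int,
    width_px: int,
    noise_sigma: float,
) -> PhantomSpec:
    if scoliotic:
        lo, hi = angles.mild if rng.random() < mild_fraction else angles.major
    else:
        lo, hi = angles.none
    angle = float(rng.uniform(lo, hi))
    if angle == 0.0:
        pattern, apex = "straight", 0.5
    elif scoliotic and rng.random() < double_fraction:
        pattern, apex = "double_S", float(rng.uniform(0.2, 0.3))
    else:
        pattern, apex = "single_C", float(rng.uniform(0.35, 0.65))
    if rng.random() < positioning_error_rate:
        tilt = float(rng.uniform(6.0, 9.0) * rng.choice([-1.0, 1.0]))
    else:
        tilt = float(np.clip(rng.normal(0.0, 1.5), -4.5, 4.5))
    return PhantomSpec(
        image_height_px=height_px,
        image_width_px=width_px,
        curve_angle_deg=angle,
        curve_pattern=pattern,
        apex_row_fraction=apex,
        noise_sigma=noise_sigma,
        tilt_deg=tilt,
        lateral_offset_px=float(np.clip(rng.normal(0.0, 4.0), -12, 12)),
        leg_asymmetry=float(np.clip(abs(rng.normal(0.0, 0.03)), 0, 0.09)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def cohort_specs(
    n: int,
    prevalence: float,
    seed: int = 0,
    angles: AngleDistributions | None = None,
    mild_fraction: float = 0.5,
    double_fraction: float = 0.3,
    positioning_error_rate: float = 0.0,
    height_px: int = 800,
    width_px: int = 300,
    noise_sigma: float = 0.02,
) -> tuple[list[PhantomSpec], pd.DataFrame]:
    """Draw the per-scan specs and truth table of a screening cohort.

    Scoliosis status is Bernoulli(prevalence) per scan; angles are drawn
    from the class-conditional uniform ranges.  Deterministic for a fixed
    seed.
    """
    if n <= 0:
        raise InvalidInputError("cohort size n must be positive")
    if not 0.0 <= prevalence < 1.0:
        raise InvalidInputError("prevalence must lie in [0, 1)")
    angles = angles or AngleDistributions()
    rng = np.random.default_rng(seed)
    specs, rows = [], []
    for i in range(n):
        scoliotic = bool(rng.random() < prevalence)
        sp = _draw_spec(
            rng, i, scoliotic, angles, mild_fraction, double_fraction,
            positioning_error_rate, height_px, width_px, noise_sigma,
        )
        specs.append(sp)
        rows.append(
            {
                "image_id": f"cohort_{i:05d}",
                "true_angle_deg": sp.curve_angle_deg,
                "true_class": grade_curve(sp.curve_angle_deg),
                "tilt_deg": sp.tilt_deg,
                "offset_px": sp.lateral_offset_px,
                "positioning_error_flag": bool(
                    abs(sp.tilt_deg) > POSITIONING_TILT_DEG
                    or abs(sp.lateral_offset_px) > POSITIONING_OFFSET_FRAC * sp.image_width_px
                    or sp.leg_asymmetry > POSITIONING_ASYM
                ),
                "seed": sp.seed,
            }
        )
    return specs, pd.DataFrame(rows)


def generate_cohort(
    n: int,
    prevalence: float,
    seed: int = 0,
    stream: bool = False,
    **kwargs,
) -> tuple[list[tuple[DxaImage, GroundTruth]] | Iterator[tuple[DxaImage, GroundTruth]], pd.DataFrame]:
    """Generate a cohort of phantoms plus its truth table.

    With ``stream=True`` the first element is a lazy iterator (one image in
    memory at a time), which is how batch drivers should consume large
    cohorts.
    """
    specs, truth = cohort_specs(n, prevalence, seed=seed, **kwargs)

    def _iter():
        for sp, image_id in zip(specs, truth["image_id"]):
            img, gt = generate_phantom(sp)
            img.image_id = image_id
            yield img, gt

    return (_iter() if stream else list(_iter())), truth


def write_cohort(
    out_dir: str | Path,
    n: int,
    prevalence: float,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Write a cohort as 16-bit PNGs plus a ``truth.csv`` table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantoms, truth = generate_cohort(n, prevalence, seed=seed, stream=True, **kwargs)
    for img, _ in phantoms:
        save_image(img, out_dir / f"{img.image_id}.png")
    truth.to_csv(out_dir / "truth.csv", index=False)
    return truth
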