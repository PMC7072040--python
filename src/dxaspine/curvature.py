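"""Curvature quantification, grading and scoring.

The lateral curvature statistic is a supine Cobb analogue: the range of the
tangent angle theta(row) = arctan(d column / d row) along the smoothed spinal
midline, in degrees.  A perfectly vertical midline has angle 0; the angle is
invariant under left-right mirroring and (to first order) under rigid
rotation of the whole body, which only shifts every tangent by the same
amount.

Grades follow the three-class screening scheme used for supine whole-body
scans: no scoliosis below 6 degrees, a small curve at 6-10 degrees, and a
curve above 10 degrees.  The continuous "suspiciousness" score collapses the
scoliotic classes into one monotone confidence in [0, 1], realised here as a
logistic function of the measured angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.signal import find_peaks

from .anatomy import BodySegmentation, Midline
from .config import PipelineConfig
from .errors import InsufficientSpineError, InvalidInputError

GRADE_NONE = "none"
GRADE_MILD = "mild_6_10"
GRADE_MAJOR = "major_gt_10"

#: Lower boundary (degrees) of the mild scoliosis class.
MILD_THRESHOLD_DEG = 6.0
#: Boundary (degrees) between the mild and major classes; 10.0 itself is mild.
MAJOR_THRESHOLD_DEG = 10.0

_MIN_MIDLINE_POINTS = 10


@dataclass(frozen=True)
class CurveMeasurement:
    """Result of measuring one midline."""

    angle_deg: float
    n_curves: int
    apex_rows: tuple[float, ...]
    grade: str


@dataclass(frozen=True)
class ScoliosisScore:
    """Continuous outputs attached to one scan."""

    suspiciousness: float
    positioning_score: float
    excluded: bool


def grade_curve(angle_deg: float) -> str:
    """Map a curve angle to the three-class grade.

    Boundaries: [0, 6) -> none, [6, 10] -> mild_6_10, (10, inf) -> major_gt_10.
    """
    if not np.isfinite(angle_deg) or angle_deg < 0:
        raise InvalidInputError(f"angle must be a non-negative number, got {angle_deg}")
    if angle_deg < MILD_THRESHOLD_DEG:
        return GRADE_NONE
    if angle_deg <= MAJOR_THRESHOLD_DEG:
        return GRADE_MILD
    return GRADE_MAJOR


def measure_curvature(
    midline: Midline, config: PipelineConfig | None = None
) -> CurveMeasurement:
    """Measure the tangent-angle range of a midline.

    The midline columns are fitted with a cubic smoothing spline in the row
    coordinate; theta is evaluated from the spline derivative on a dense row
    grid, trimming a small fraction at each end where spline derivatives are
    least reliable.  ``angle_deg = max(theta) - min(theta)``.

    ``n_curves`` counts sign-alternating segments of the centred tangent
    profile: the number of sign changes of ``theta - mean(theta)`` plus one,
    ignoring samples within a small dead band of the mean.
    """
    cfg = config or PipelineConfig()
    pts = np.asarray(midline.points, dtype=float)
    if pts.shape[0] < _MIN_MIDLINE_POINTS:
        raise InsufficientSpineError(
            f"midline has {pts.shape[0]} points; need >= {_MIN_MIDLINE_POINTS}"
        )
    rows, cols = pts[:, 0], pts[:, 1]

    lam = cfg.midline_smoothing_lam
    spline = make_smoothing_spline(rows, cols, lam=lam if lam > 0 else None)
    trim = cfg.tangent_trim_fraction * (rows[-1] - rows[0])
    dense = np.linspace(rows[0] + trim, rows[-1] - trim, max(200, 4 * len(rows)))
    slope = spline.derivative()(dense)
    theta = np.degrees(np.arctan(slope))
    angle = float(theta.max() - theta.min())

    centred = theta - theta.mean()
    dead = max(1e-6, 0.02 * (theta.max() - theta.min()))
    signs = np.sign(centred[np.abs(centred) > dead])
    n_changes = int(np.count_nonzero(np.diff(signs))) if signs.size else 0
    n_curves = n_changes + 1

    # apexes: local maxima of |deviation from the endpoint chord|
    chord = np.interp(rows, [rows[0], rows[-1]], [cols[0], cols[-1]])
    dev = np.abs(cols - chord)
    if dev.max() > 1e-9:
        peaks, _ = find_peaks(dev, prominence=0.05 * dev.max())
        apex_rows = tuple(float(rows[p]) for p in peaks)
        if not apex_rows:
            apex_rows = (float(rows[int(np.argmax(dev))]),)
    else:
        apex_rows = ()

    return CurveMeasurement(
        angle_deg=angle, n_curves=n_curves, apex_rows=apex_rows, grade=grade_curve(angle)
    )


def suspiciousness(
    measurement: CurveMeasurement | float, config: PipelineConfig | None = None
) -> float:
    """Logistic suspiciousness score in (0, 1), strictly increasing in angle.

    ``score = 1 / (1 + exp(-k * (angle - midpoint)))`` with the calibration
    midpoint (default 6 deg, the lower scoliosis boundary) scoring exactly
    0.5 and steepness k (default 1.5 per degree) controlling how fast the
    score saturates; score(10 deg) ~= 0.9975 with the defaults.
    """
    cfg = config or PipelineConfig()
    if cfg.score_midpoint_deg <= 0 or cfg.score_steepness_per_deg <= 0:
        raise InvalidInputError("score calibration (midpoint, steepness) must be positive")
    angle = measurement.angle_deg if isinstance(measurement, CurveMeasurement) else float(measurement)
    z = cfg.score_steepness_per_deg * (angle - cfg.score_midpoint_deg)
    return float(1.0 / (1.0 + np.exp(-z)))


def positioning_components(
    tilt_deg: float, offset_frac: float, asymmetry: float, config: PipelineConfig | None = None
) -> tuple[float, float, float]:
    """Normalised positioning-error components, each clipped to [0, 1]."""
    cfg = config or PipelineConfig()
    return (
        min(abs(tilt_deg) / cfg.tilt_max_deg, 1.0),
        min(abs(offset_frac) / cfg.offset_max_frac, 1.0),
        min(abs(asymmetry) / cfg.asym_max, 1.0),
    )


def positioning_error_score(
    seg: BodySegmentation, config: PipelineConfig | None = None
) -> float:
    """Positioning-error score in [0, 1] from a body segmentation.

    The score is the maximum of three normalised components measured on the
    segmentation: whole-body principal-axis tilt (normaliser 10 deg),
    lateral centroid offset from the image centre (normaliser 15% of the
    image width) and leg-length asymmetry (normaliser 0.2).  A perfectly
    posed, centred body scores 0; scans scoring above the exclusion
    threshold (default 0.5) are excluded from diagnostic statistics.
    """
    cfg = config or PipelineConfig()
    tilt = seg.principal_axis_tilt_deg()
    offset = seg.centroid_offset_frac()
    asym = seg.leg_length_asymmetry()
    return float(max(positioning_components(tilt, offset, asym, cfg)))


def score_scan(
    measurement: CurveMeasurement,
    seg: BodySegmentation,
    config: PipelineConfig | None = None,
) -> ScoliosisScore:
    """Bundle the continuous outputs for one scan.

    ``excluded`` is true exactly when the positioning score exceeds the
    configured exclusion threshold (strict inequality).
    """
    cfg = config or PipelineConfig()
    pos = positioning_error_score(seg, cfg)
    return ScoliosisScore(
        suspiciousness=suspiciousness(measurement, cfg),
        positioning_score=pos,
        excluded=bool(pos > cfg.positioning_exclusion_threshold),
    )


def binarize(score: float, cutoff: float) -> bool:
    """Binary scoliosis call: ``True`` iff ``score > cutoff`` (strict)."""
    if not 0.0 <= score <= 1.0:
        raise InvalidInputError(f"score {score} outside [0, 1]")
    if not 0.0 <= cutoff <= 1.0:
        raise InvalidInputError(f"cutoff {cutoff} outside [0, 1]")
    return bool(score > cutoff)
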