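"""Heuristic anatomical segmentation and mid-spine midline extraction.

A supine whole-body scan is expected to show five structures: a head, a
spine, a pelvis and two legs.  Segmentation proceeds by simple, explicit
rules on the binarised silhouette:

1. Otsu threshold -> largest connected foreground component (the body).
2. Row-wise width profile: the neck is the width minimum near the top and
   separates the head; the pelvis is the widest band below mid-torso; the
   crotch is where the silhouette first splits into two parallel runs, and
   everything below it forms the two leg components.
3. The spine is the medial high-intensity ridge between neck and pelvis,
   found by seeding at the row of strongest medial contrast and tracking
   the per-row intensity maximum up and down within a narrow window.

Torso soft tissue that belongs to none of the five structures keeps the
background label, mirroring how arms are ignored.

The mid-spine map is the classical counterpart of a spine-centre heatmap: a
per-row Gaussian bump centred on the intensity-weighted centroid column of
that row's spine pixels, normalised to peak 1 per row and zero outside a
dilation of the spine mask.  Its row-wise centre of mass, smoothed by a
cubic smoothing spline, is the midline handed to curvature measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_smoothing_spline
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .config import PipelineConfig
from .errors import AnatomyViolationError, InsufficientSpineError

LABELS = ("background", "head", "spine", "pelvis", "left_leg", "right_leg")
LABEL_IDS = {name: i for i, name in enumerate(LABELS)}


@dataclass
class RegionStats:
    pixel_count: int
    bbox: tuple[int, int, int, int]  # min_row, min_col, max_row, max_col (inclusive)


@dataclass
class BodySegmentation:
    """Per-pixel anatomical labels plus cached region statistics."""

    labels: np.ndarray  # int grid over LABEL_IDS
    region_stats: dict[str, RegionStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.region_stats:
            for name, lid in LABEL_IDS.items():
                if name == "background":
                    continue
                mask = self.labels == lid
                if mask.any():
                    rows, cols = np.nonzero(mask)
                    self.region_stats[name] = RegionStats(
                        pixel_count=int(mask.sum()),
                        bbox=(int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())),
                    )

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABEL_IDS[name]

    def foreground(self) -> np.ndarray:
        return self.labels != LABEL_IDS["background"]

    # --- positioning measurements -------------------------------------------------

    def body_mask(self) -> np.ndarray:
        """Union of all labelled structures (the analysed silhouette)."""
        return self.labels > 0

    def principal_axis_tilt_deg(self) -> float:
        """Signed angle between the body's principal axis and the vertical."""
        mask = self.body_mask()
        props = regionprops(mask.astype(np.uint8))[0]
        # regionprops orientation: angle between the row axis and the major
        # axis, in (-pi/2, pi/2]; a vertical body has orientation ~0.  The
        # sign is flipped so that a head leaning toward larger columns gives
        # a positive tilt.
        return float(-np.degrees(props.orientation))

    def centroid_offset_frac(self) -> float:
        """Lateral body-centroid offset from the image centre, as width fraction."""
        mask = self.body_mask()
        _, cols = np.nonzero(mask)
        centre = (self.labels.shape[1] - 1) / 2.0
        return float((cols.mean() - centre) / self.labels.shape[1])

    def leg_length_asymmetry(self) -> float:
        """1 - (shorter leg length / longer leg length), from leg bounding boxes."""
        lens = []
        for name in ("left_leg", "right_leg"):
            st = self.region_stats.get(name)
            if st is None:
                return 1.0
            lens.append(st.bbox[2] - st.bbox[0] + 1)
        return float(1.0 - min(lens) / max(lens))


@dataclass
class MidSpineMap:
    """Per-pixel spine-centre likelihood in [0, 1]."""

    likelihood: np.ndarray

    def supported_rows(self) -> np.ndarray:
        return np.nonzero(self.likelihood.max(axis=1) > 0)[0]


@dataclass
class Midline:
    """Ordered (row, column) spine-centre curve, head to pelvis.

    Rows are strictly increasing integers; columns are real-valued
    (sub-pixel).
    """

    points: np.ndarray  # (n, 2) float, [:, 0]=row, [:, 1]=column

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("midline points must be an (n, 2) array")
        if pts.shape[0] >= 2 and not np.all(np.diff(pts[:, 0]) > 0):
            raise ValueError("midline rows must be strictly increasing")
        self.points = pts

    @property
    def rows(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.points[:, 1]


# ----------------------------------------------------------------------------------
# segmentation
# ----------------------------------------------------------------------------------


def _row_runs(row_mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Contiguous True runs of at least min_len pixels, as (start, stop)."""
    padded = np.diff(np.concatenate(([0], row_mask.view(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    stops = np.nonzero(padded == -1)[0]
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_len]


def segment_body(image, config: PipelineConfig | None = None) -> BodySegmentation:
    """Segment a standardised whole-body image into the five structures.

    Raises :class:`AnatomyViolationError` naming the failed expectation when
    the silhouette does not contain a head candidate, a two-leg split, a
    pelvis band or a trackable spine ridge.
    """
    cfg = config or PipelineConfig()
    px = image.pixels
    h, w = px.shape
    scale = cfg.scale(h)

    thr = threshold_otsu(px)
    fg = px > thr
    comps = cc_label(fg, connectivity=2)
    if comps.max() == 0:
        raise AnatomyViolationError("head", "empty foreground: no body found")
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    fg = comps == int(np.argmax(sizes))

    widths = fg.sum(axis=1)
    body_rows = np.nonzero(widths)[0]
    top, bot = int(body_rows[0]), int(body_rows[-1])
    body_h = bot - top + 1
    if body_h < 20:
        raise AnatomyViolationError("head", "body too short to partition")

    # neck: width minimum in the upper part of the body
    band = np.arange(top + max(2, int(0.03 * body_h)), top + int(0.30 * body_h))
    neck_row = int(band[np.argmin(widths[band])])
    head_mask = fg.copy()
    head_mask[neck_row:] = False
    if head_mask.sum() < 20:
        raise AnatomyViolationError("head", "no head component above the neck minimum")

    # crotch: first row below mid-body where the silhouette splits into two
    # runs of leg-like width, and stays split (guards against interpolation
    # slivers at the tilted pelvis corners)
    min_run = max(3, int(0.04 * w))
    persist = max(3, int(0.01 * body_h))
    crotch_row = None
    for r in range(top + int(0.45 * body_h), bot + 1 - persist):
        if all(len(_row_runs(fg[rr], min_run)) >= 2 for rr in range(r, r + persist)):
            crotch_row = r
            break
    if crotch_row is None:
        raise AnatomyViolationError("legs", "silhouette never splits into two legs")

    legs_region = fg.copy()
    legs_region[:crotch_row] = False
    leg_comps = cc_label(legs_region, connectivity=2)
    leg_sizes = np.bincount(leg_comps.ravel())
    leg_sizes[0] = 0
    big = [i for i in np.argsort(leg_sizes)[::-1] if leg_sizes[i] >= 30 * scale * scale][:2]
    if len(big) < 2:
        raise AnatomyViolationError("legs", f"expected two legs, found {len(big)} component(s)")
    cent_cols = [np.nonzero(leg_comps == i)[1].mean() for i in big]
    left_id, right_id = (big[0], big[1]) if cent_cols[0] < cent_cols[1] else (big[1], big[0])

    # pelvis: widest band between the lower torso and the crotch
    lo = top + int(0.55 * (crotch_row - top))
    if lo >= crotch_row:
        raise AnatomyViolationError("pelvis", "no room for a pelvis band")
    pel_band = np.arange(lo, crotch_row)
    wmax = widths[pel_band].max()
    wide = pel_band[widths[pel_band] >= 0.85 * wmax]
    pelvis_top = int(wide[0])
    pelvis_mask = fg.copy()
    pelvis_mask[:pelvis_top] = False
    pelvis_mask[crotch_row:] = False
    if not pelvis_mask.any():
        raise AnatomyViolationError("pelvis", "empty pelvis band")

    spine_mask = _track_spine_ridge(px, fg, neck_row, crotch_row, cfg, scale)

    labels = np.zeros((h, w), dtype=np.int16)
    labels[head_mask] = LABEL_IDS["head"]
    labels[pelvis_mask] = LABEL_IDS["pelvis"]
    labels[leg_comps == left_id] = LABEL_IDS["left_leg"]
    labels[leg_comps == right_id] = LABEL_IDS["right_leg"]
    labels[spine_mask] = LABEL_IDS["spine"]  # spine wins over pelvis overlap
    return BodySegmentation(labels=labels)


def _track_spine_ridge(
    px: np.ndarray,
    fg: np.ndarray,
    neck_row: int,
    crotch_row: int,
    cfg: PipelineConfig,
    scale: float,
) -> np.ndarray:
    """Track the medial high-intensity ridge between neck and crotch."""
    h, w = px.shape
    smooth = ndimage.gaussian_filter1d(px, sigma=max(1.0, 1.5 * scale), axis=1)
    halfband = max(2, int(round(cfg.spine_band_halfwidth_px * scale)))
    track_win = max(2, int(round(cfg.ridge_track_halfwidth_px * scale)))

    def torso_span(r: int) -> tuple[int, int] | None:
        cols = np.nonzero(fg[r])[0]
        if cols.size < 4:
            return None
        return int(cols[0]), int(cols[-1])

    # seed: strongest medial contrast in the torso
    best = None
    for r in range(neck_row + 1, crotch_row):
        span = torso_span(r)
        if span is None:
            continue
        c0, c1 = span
        third = (c1 - c0) // 3
        lo, hi = c0 + third, c1 - third
        if hi <= lo:
            continue
        seg = smooth[r, lo:hi]
        med = np.median(smooth[r, c0 : c1 + 1])
        contrast = seg.max() - med
        if best is None or contrast > best[0]:
            best = (contrast, r, lo + int(np.argmax(seg)))
    if best is None or best[0] <= 0:
        raise AnatomyViolationError("spine", "no medial intensity ridge found")
    seed_contrast, seed_row, seed_col = best
    stop_contrast = cfg.ridge_stop_fraction * seed_contrast

    spine = np.zeros((h, w), dtype=bool)

    def walk(rows) -> None:
        prev = seed_col
        for r in rows:
            span = torso_span(r)
            if span is None:
                break
            c0, c1 = span
            lo = max(c0, prev - track_win)
            hi = min(c1, prev + track_win) + 1
            if hi <= lo:
                break
            ridge = lo + int(np.argmax(smooth[r, lo:hi]))
            med = np.median(smooth[r, c0 : c1 + 1])
            if smooth[r, ridge] - med < stop_contrast:
                break
            cut = 0.5 * (smooth[r, ridge] + med)
            wlo, whi = max(c0, ridge - halfband), min(c1, ridge + halfband) + 1
            cols = np.arange(wlo, whi)
            spine[r, cols[px[r, wlo:whi] > cut]] = True
            spine[r, ridge] = True
            prev = ridge

    walk(range(seed_row, crotch_row))
    walk(range(seed_row - 1, neck_row, -1))

    if spine.sum() < 10:
        raise AnatomyViolationError("spine", "spine ridge support too small")
    return spine


# ----------------------------------------------------------------------------------
# mid-spine map and midline
# ----------------------------------------------------------------------------------


def compute_midspine_map(image, seg: BodySegmentation, config: PipelineConfig | None = None) -> MidSpineMap:
    """Build the per-row spine-centre likelihood map.

    For every row with spine pixels, the likelihood is a Gaussian bump (sigma
    from config, expressed at the standard height) centred on the
    intensity-weighted centroid column of the row's spine pixels, using
    baseline-subtracted weights so surrounding soft tissue does not bias the
    centroid.  Each supported row is normalised to peak 1; the map is zero
    outside a dilation of the spine mask.
    """
    cfg = config or PipelineConfig()
    px = image.pixels
    h, w = px.shape
    scale = cfg.scale(h)
    sigma = cfg.midspine_sigma_px * scale

    spine = seg.mask("spine")
    if not spine.any():
        raise AnatomyViolationError("spine", "segmentation contains no spine region")

    pad = max(1, int(np.ceil(2 * sigma)))
    support = ndimage.binary_dilation(spine, structure=np.ones((1, 2 * pad + 1), dtype=bool))

    like = np.zeros((h, w), dtype=np.float64)
    cols_idx = np.arange(w, dtype=float)
    for r in np.nonzero(spine.any(axis=1))[0]:
        cols = np.nonzero(spine[r])[0]
        lo, hi = cols[0] - pad, cols[-1] + pad + 1
        lo, hi = max(0, lo), min(w, hi)
        window = px[r, lo:hi]
        wgt = np.clip(window - window.min(), 0.0, None)
        if wgt.sum() <= 0:
            continue
        centroid = float(np.sum(wgt * np.arange(lo, hi)) / wgt.sum())
        bump = np.exp(-((cols_idx - centroid) ** 2) / (2.0 * sigma**2))
        bump[~support[r]] = 0.0
        peak = bump.max()
        if peak > 0:
            like[r] = bump / peak
    return MidSpineMap(likelihood=like)


def extract_midline(mid_map: MidSpineMap, config: PipelineConfig | None = None) -> Midline:
    """Extract the sub-pixel midline from a mid-spine map.

    Per supported row the column is the centre of mass of the row's
    likelihood; the resulting curve is smoothed with a cubic smoothing
    spline (penalty from config) before export so that tangent angles are
    well defined.
    """
    cfg = config or PipelineConfig()
    like = mid_map.likelihood
    rows = mid_map.supported_rows()
    if rows.size < 10:
        raise InsufficientSpineError(f"only {rows.size} supported rows; need >= 10")
    cols_idx = np.arange(like.shape[1], dtype=float)
    raw_cols = np.array([np.sum(like[r] * cols_idx) / np.sum(like[r]) for r in rows])

    lam = cfg.midline_smoothing_lam
    spline = make_smoothing_spline(rows.astype(float), raw_cols, lam=lam if lam > 0 else None)
    smoothed = spline(rows.astype(float))
    return Midline(points=np.column_stack([rows.astype(float), smoothed]))
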