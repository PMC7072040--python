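"""End-to-end scan processing and batch evaluation.

``process_scan`` runs one image through standardise -> segment -> mid-spine
map -> midline -> curvature -> scores and returns a flat record.
``run_batch`` maps it over a directory (or iterable) of scans, joins the
optional truth table, applies the positioning-error exclusion rule *before*
any diagnostic statistic, and emits the cut-off sweep and AUC.

Per-scan failures are recorded in the record's ``status`` field and never
abort the batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import anatomy, curvature, diagnostics
from .config import PipelineConfig
from .errors import DxaSpineError
from .preprocessing import DxaImage, load_image, standardize_height

log = logging.getLogger("dxaspine")

RECORD_COLUMNS = [
    "image_id", "status", "angle_deg", "grade", "suspiciousness",
    "positioning_score", "excluded", "binary_call",
]


@dataclass
class ScanRecord:
    """Flat per-scan output of the pipeline.

    ``binary_call`` is None for excluded or failed scans: an excluded scan
    carries no diagnostic decision.
    """

    image_id: str
    status: str = "ok"
    angle_deg: float | None = None
    grade: str | None = None
    suspiciousness: float | None = None
    positioning_score: float | None = None
    excluded: bool | None = None
    binary_call: bool | None = None


def process_scan(image: DxaImage | str | Path, config: PipelineConfig | None = None) -> ScanRecord:
    """Run the full pipeline on one scan; errors land in ``status``."""
    cfg = config or PipelineConfig()
    try:
        img = image if isinstance(image, DxaImage) else load_image(image)
        std = standardize_height(img, cfg.target_height_px)
        seg = anatomy.segment_body(std, cfg)
        mid_map = anatomy.compute_midspine_map(std, seg, cfg)
        midline = anatomy.extract_midline(mid_map, cfg)
        meas = curvature.measure_curvature(midline, cfg)
        score = curvature.score_scan(meas, seg, cfg)
        call = None if score.excluded else curvature.binarize(score.suspiciousness, cfg.cutoff)
        rec = ScanRecord(
            image_id=img.image_id,
            angle_deg=meas.angle_deg,
            grade=meas.grade,
            suspiciousness=score.suspiciousness,
            positioning_score=score.positioning_score,
            excluded=score.excluded,
            binary_call=call,
        )
        log.info("scan %s: ok angle=%.2f excluded=%s", img.image_id, meas.angle_deg, score.excluded)
        return rec
    except DxaSpineError as exc:
        image_id = image.image_id if isinstance(image, DxaImage) else Path(image).stem
        log.warning("scan %s: %s", image_id, exc)
        return ScanRecord(image_id=image_id, status=f"error: {exc}")


def records_to_frame(records: Iterable[ScanRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=RECORD_COLUMNS)


def run_batch(
    images: str | Path | Iterable[DxaImage],
    truth: pd.DataFrame | str | Path | None = None,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Process many scans and, when truth is available, evaluate them.

    ``images`` may be a directory of PNG/TIFF files or an iterable of
    in-memory images.  The optional truth table must carry ``image_id`` and
    ``true_class`` (any class other than ``"none"`` counts as scoliosis).
    Excluded scans are dropped before every diagnostic statistic.
    """
    cfg = config or PipelineConfig()

    skipped = 0
    records: list[ScanRecord] = []
    if isinstance(images, (str, Path)):
        paths = sorted(p for p in Path(images).iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"})
        for p in paths:
            try:
                img = load_image(p)
            except Exception as exc:  # unreadable file: log and skip
                log.warning("skipping unreadable file %s: %s", p, exc)
                skipped += 1
                continue
            records.append(process_scan(img, cfg))
    else:
        for img in images:
            records.append(process_scan(img, cfg))

    frame = records_to_frame(records)
    report: dict = {
        "n_scans": int(len(frame)),
        "n_failed": int((frame["status"] != "ok").sum()),
        "n_excluded": int(frame["excluded"].fillna(False).sum()),
        "n_skipped_files": skipped,
    }

    if truth is not None:
        truth_df = truth if isinstance(truth, pd.DataFrame) else pd.read_csv(truth)
        merged = frame.merge(truth_df, on="image_id", how="inner", validate="one_to_one")
        usable = merged[(merged["status"] == "ok") & (~merged["excluded"].astype(bool))]
        report["n_evaluated"] = int(len(usable))
        if len(usable) >= 2 and usable["true_class"].nunique() > 1:
            y = (usable["true_class"] != "none").to_numpy().astype(int)
            s = usable["suspiciousness"].to_numpy(dtype=float)
            rows = diagnostics.sweep_cutoffs(
                s, y, cfg.sweep_cutoffs,
                prevalence=cfg.prevalence, n_projection=cfg.projection_n, seed=cfg.seed,
            )
            report["auc"] = rows[0].auc.auc
            report["auc_ci"] = [rows[0].auc.ci_low, rows[0].auc.ci_high]
            report["sweep"] = [
                {
                    "cutoff": r.cutoff,
                    "sensitivity_pct": round(100 * r.sensitivity, 1),
                    "specificity_pct": round(100 * r.specificity, 1),
                    "ppv_pct": r.projection.ppv_pct,
                    "npv_pct": r.projection.npv_pct,
                    "predicted_prevalence_pct": r.projection.predicted_prevalence_pct,
                }
                for r in rows
            ]
    return frame, report


def write_outputs(frame: pd.DataFrame, report: dict, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_dir / "records.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
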