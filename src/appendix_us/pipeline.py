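"""End-to-end orchestration: stretch -> binarize -> label/filter ->
fascia bridge -> ROI -> fuzzy ART -> quantize -> dark-binarize -> erode ->
select -> measure.

The pipeline is fully deterministic: no stage uses randomness (seeds live
only in the phantom generator).  Expected failure modes (degenerate
contrast, no fascia, no surviving candidate) are returned as structured
failure records, not exceptions — failure is data at the batch level.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import extract as ext
from . import fascia as fas
from . import fuzzyart as fart
from . import preprocess as pre
from .config import PipelineConfig
from .errors import ImageFormatError, StageFailure
from .imgio import (
    BinaryImage,
    GrayscaleImage,
    binarize_at,
    read_image,
    write_grayscale,
    write_mask,
)
from .phantom import evaluate

logger = logging.getLogger("appendix_us")

_IMAGE_SUFFIXES = {".png", ".bmp", ".tif", ".tiff", ".dcm", ".dicom"}
_TRUTH_SUFFIX = "_appendix"


@dataclass
class PipelineResult:
    """Outcome of one pipeline run: either a candidate or a structured
    failure record ``{"stage": ..., "reason": ...}``, plus per-stage
    artifacts for inspection and debug dumps."""

    ok: bool
    candidate: ext.AppendixCandidate | None = None
    failure: dict | None = None
    artifacts: dict = field(default_factory=dict)

    @property
    def failed_stage(self) -> str | None:
        return self.failure["stage"] if self.failure else None


def run_pipeline(
    img: GrayscaleImage,
    cfg: PipelineConfig | None = None,
    debug_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full extraction pipeline on one grayscale image."""
    cfg = cfg or PipelineConfig()
    artifacts: dict = {}
    try:
        stage = "stretch"
        bounds = pre.compute_stretch_bounds(
            img, cfg.stretch.low_frac, cfg.stretch.high_frac
        )
        stretched = pre.ends_in_stretch(img, bounds)
        artifacts["stretched"] = stretched

        stage = "binarize"
        binary = pre.max_min_binarize(stretched)
        artifacts["binary"] = binary

        stage = "label_filter"
        labeled = pre.label_regions(binary, cfg.labeling.connectivity)
        cleaned = pre.remove_small_regions(labeled, cfg.noise_filter.min_area)
        artifacts["cleaned"] = cleaned

        stage = "fascia"
        cleaned_labeled = pre.label_regions(cleaned, cfg.labeling.connectivity)
        boundary = fas.extract_bottom_boundary(
            cleaned,
            width_frac=cfg.fascia.width_frac,
            bottom_tol_frac=cfg.fascia.bottom_tol_frac,
            connectivity=cfg.labeling.connectivity,
            labeled=cleaned_labeled,
        )
        knots = boundary.thin(cfg.fascia.knot_stride)
        curve = fas.fit_natural_spline(knots)
        bridged = fas.bridge_gaps(cleaned, curve)
        artifacts["boundary"] = boundary
        artifacts["curve"] = curve
        artifacts["bridged"] = bridged

        stage = "roi"
        roi = fas.roi_below_curve(img, curve, cfg.roi.margin_px)
        artifacts["roi"] = roi

        stage = "fuzzyart"
        assign, state = fart.cluster_roi(stretched, roi, cfg.fuzzyart.to_params())
        quantized = fart.quantize(stretched, roi, assign)
        artifacts["assignment"] = assign
        artifacts["state"] = state
        artifacts["quantized"] = quantized

        stage = "extract"
        dark = ext.binarize_dark_clusters(quantized, assign, cfg.extract.dark_quantile)
        eroded = ext.erode(dark, cfg.extract.erode_radius, cfg.extract.erode_iterations)
        artifacts["dark"] = dark
        artifacts["eroded"] = eroded
        candidate = ext.select_appendix(
            eroded, img, cfg.extract.min_area, reconstruct_in=dark
        )
        candidate = ext.measure_candidate(candidate, img.pixel_spacing)
        artifacts["candidate_mask"] = candidate.mask
        result = PipelineResult(ok=True, candidate=candidate, artifacts=artifacts)
    except StageFailure as exc:
        result = PipelineResult(
            ok=False,
            failure={"stage": getattr(exc, "stage", stage), "reason": str(exc)},
            artifacts=artifacts,
        )
    if debug_dir is not None:
        _dump_debug(result, Path(debug_dir))
    return result


def _dump_debug(result: PipelineResult, debug_dir: Path) -> None:
    debug_dir.mkdir(parents=True, exist_ok=True)
    for name, obj in result.artifacts.items():
        if isinstance(obj, GrayscaleImage):
            write_grayscale(obj, debug_dir / f"{name}.png")
        elif isinstance(obj, BinaryImage):
            write_mask(obj, debug_dir / f"{name}.png")
        elif isinstance(obj, fas.RoiMask):
            write_mask(obj.mask, debug_dir / f"{name}.png")
        elif isinstance(obj, fas.BoundaryPoints):
            with open(debug_dir / f"{name}.csv", "w", encoding="utf-8") as fh:
                fh.write("x,y\n")
                for x, y in zip(obj.xs, obj.ys):
                    fh.write(f"{x},{y}\n")
        elif isinstance(obj, fart.FuzzyARTState):
            with open(debug_dir / "clusters.txt", "w", encoding="utf-8") as fh:
                for j, (w, c) in enumerate(zip(obj.weights, obj.counts)):
                    fh.write(f"cluster {j}: prototype={w:.6f} pixels={c}\n")


@dataclass
class BatchRecord:
    name: str
    ok: bool
    failed_stage: str | None = None
    iou: float | None = None
    dice: float | None = None
    success: bool | None = None
    error: str | None = None


@dataclass
class BatchSummary:
    records: list[BatchRecord]
    errors: list[str]

    @property
    def n_images(self) -> int:
        return len(self.records)

    @property
    def extraction_rate(self) -> float | None:
        """Fraction of evaluable images (with truth) whose IoU >= 0.5;
        falls back to the fraction with any candidate when no truths exist."""
        scored = [r for r in self.records if r.success is not None]
        if scored:
            return sum(r.success for r in scored) / len(scored)
        if self.records:
            return sum(r.ok for r in self.records) / len(self.records)
        return None


def run_batch(
    directory: str | Path,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> BatchSummary:
    """Run the pipeline over a directory of images.

    Truth masks named ``<stem>_appendix.png`` (as written by the phantom
    battery) are used to score IoU/Dice; success = IoU >= 0.5.  Unreadable
    files are reported in the summary's error list and the run continues.
    """
    cfg = cfg or PipelineConfig()
    directory = Path(directory)
    records: list[BatchRecord] = []
    errors: list[str] = []
    paths = sorted(
        p
        for p in directory.iterdir()
        if p.suffix.lower() in _IMAGE_SUFFIXES and not p.stem.endswith(_TRUTH_SUFFIX)
        and not p.stem.endswith("_fascia") and not p.stem.endswith("_ascites")
    )
    if not paths:
        logger.warning("no images found in %s", directory)
    for path in paths:
        try:
            img = read_image(path)
        except (ImageFormatError, OSError) as exc:
            errors.append(f"{path.name}: {exc}")
            continue
        result = run_pipeline(img, cfg)
        rec = BatchRecord(name=path.name, ok=result.ok, failed_stage=result.failed_stage)
        truth_path = path.with_name(path.stem + f"{_TRUTH_SUFFIX}.png")
        if truth_path.exists():
            truth = binarize_at(read_image(truth_path))
            if result.ok:
                scores = evaluate(result.candidate.mask, truth)
                rec.iou, rec.dice = scores.iou, scores.dice
                rec.success = scores.success
            else:
                rec.iou, rec.dice, rec.success = 0.0, 0.0, False
        records.append(rec)
    summary = BatchSummary(records=records, errors=errors)
    if out_dir is not None:
        write_batch_summary(summary, Path(out_dir))
    return summary


def write_batch_summary(summary: BatchSummary, out_dir: Path) -> None:
    """Write the per-image table as CSV and the aggregate as JSON."""
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "batch.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "ok", "failed_stage", "iou", "dice", "success"])
        for r in summary.records:
            writer.writerow([r.name, r.ok, r.failed_stage or "", r.iou, r.dice, r.success])
        writer.writerow(["TOTAL", summary.n_images, "", "", "", summary.extraction_rate])
    payload = {
        "n_images": summary.n_images,
        "extraction_rate": summary.extraction_rate,
        "errors": summary.errors,
        "records": [vars(r) for r in summary.records],
    }
    with open(out_dir / "batch.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
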