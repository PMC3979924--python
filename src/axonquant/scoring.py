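"""Binarization, segment features, long/short classification and the
normalized length score.

A projected image is thresholded (Otsu by default), connected foreground
components are extracted, and each component is classified *long* (an
intact or regenerating axon) when it satisfies all three criteria strictly:

* eccentricity of the second-central-moments ellipse  > 0.99,
* major-axis length of that ellipse                   > 200 px,
* filled area (interior holes filled)                 > 2000 px.

Everything else is *short* (degenerating debris).  The normalized length
score of the image is the fraction of foreground pixels (raw, unfilled
counts) belonging to long segments; at baseline it is 1 and it traces
Wallerian degeneration and regrowth over the post-repair time course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .io import ImageVolume, RunConfig
from .projection import ProjectedImage, sample_rois, sum_project

log = logging.getLogger("axonquant")


@dataclass
class BinaryMask:
    """Foreground mask of a projected image (pixels strictly above threshold)."""
    mask: np.ndarray                 # bool (y, x)
    threshold: float
    method: str


@dataclass
class SegmentFeatures:
    """Shape descriptors of one connected foreground segment."""
    segment_id: int
    eccentricity: float              # of the ellipse with matching 2nd central moments
    major_axis_px: float             # major-axis length of that ellipse
    filled_area_px: int              # pixel count with interior holes filled
    pixel_count: int                 # raw pixel count
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    feret_diameter_px: float         # max Feret diameter, reported for transparency


@dataclass
class ClassifiedSegments:
    """Long/short labels for every segment of one image."""
    features: list[SegmentFeatures]
    labels: list[str]                # "long" | "short", parallel to features
    thresholds: tuple[float, float, float]
    long_pixels: int = 0
    short_pixels: int = 0

    def __post_init__(self) -> None:
        self.long_pixels = sum(
            f.pixel_count for f, lab in zip(self.features, self.labels) if lab == "long"
        )
        self.short_pixels = sum(
            f.pixel_count for f, lab in zip(self.features, self.labels) if lab == "short"
        )


@dataclass
class LengthScore:
    """Per-ROI normalized length score: long pixels / all segment pixels."""
    roi_index: int
    score: float                     # NaN when the ROI has no foreground
    long_pixels: int
    total_pixels: int
    threshold: float = float("nan")

    @property
    def valid(self) -> bool:
        return self.total_pixels > 0


@dataclass
class TimeCourseTable:
    """Per-ROI scores and per-timepoint summaries over a recovery series."""
    per_roi: pd.DataFrame            # columns: timepoint, roi_index, score, ...
    summary: pd.DataFrame            # columns: timepoint, mean, sd, n


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def binarize(image: ProjectedImage, method: str = "otsu",
             threshold: float | None = None) -> BinaryMask:
    """Threshold a projected image; foreground is strictly above threshold."""
    data = image.data
    if method == "otsu":
        if np.all(data == data.flat[0]):
            raise ValueError(
                "cannot apply Otsu thresholding to a constant image; "
                "use method='fixed' with an explicit threshold"
            )
        thr = float(threshold_otsu(data))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold value")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryMask(mask=data > thr, threshold=thr, method=method)


def extract_segments(mask: BinaryMask | np.ndarray,
                     connectivity: int = 8) -> list[SegmentFeatures]:
    """Connected-component shape features under 4- or 8-connectivity.

    Eccentricity and major-axis length come from the standard
    ellipse-of-inertia construction on the component's pixel coordinates;
    the filled area counts the component with interior holes filled.  An
    empty mask yields an empty list.
    """
    arr = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = cc_label(arr, connectivity=1 if connectivity == 4 else 2)
    out: list[SegmentFeatures] = []
    for rp in regionprops(lab):
        out.append(SegmentFeatures(
            segment_id=int(rp.label),
            eccentricity=float(rp.eccentricity),
            major_axis_px=float(rp.axis_major_length),
            filled_area_px=int(rp.area_filled),
            pixel_count=int(rp.area),
            bbox=tuple(rp.bbox),
            feret_diameter_px=float(rp.feret_diameter_max),
        ))
    return out


def classify_segment(features: SegmentFeatures, config: RunConfig) -> str:
    """"long" iff all three strict inequalities hold, else "short"."""
    is_long = (
        features.eccentricity > config.eccentricity_threshold
        and features.major_axis_px > config.major_axis_threshold_px
        and features.filled_area_px > config.filled_area_threshold_px
    )
    return "long" if is_long else "short"


def classify_segments(features: list[SegmentFeatures],
                      config: RunConfig) -> ClassifiedSegments:
    labels = [classify_segment(f, config) for f in features]
    return ClassifiedSegments(
        features=features,
        labels=labels,
        thresholds=(config.eccentricity_threshold, config.major_axis_threshold_px,
                    config.filled_area_threshold_px),
    )


def normalized_length_score(classified: ClassifiedSegments,
                            roi_index: int = -1,
                            threshold: float = float("nan")) -> LengthScore:
    """Long-segment pixels / all-segment pixels (raw counts both)."""
    total = classified.long_pixels + classified.short_pixels
    if total == 0:
        log.warning("ROI %d has no foreground segments; score flagged invalid", roi_index)
        return LengthScore(roi_index, float("nan"), 0, 0, threshold)
    return LengthScore(roi_index, classified.long_pixels / total,
                       classified.long_pixels, total, threshold)


def score_projection(image: ProjectedImage, config: RunConfig) -> tuple[LengthScore, BinaryMask, ClassifiedSegments]:
    """Run binarize -> extract -> classify -> score on one projected image."""
    bm = binarize(image, config.binarization, config.fixed_threshold)
    feats = extract_segments(bm, config.connectivity)
    classified = classify_segments(feats, config)
    return normalized_length_score(classified, image.roi_index, bm.threshold), bm, classified


def score_volume(
    volume: ImageVolume,
    config: RunConfig,
    region: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
    keep_intermediates: bool = False,
):
    """Score a full volume: sample ROIs, project, binarize, classify, score.

    Returns a list of per-ROI :class:`LengthScore`; with
    ``keep_intermediates`` also a parallel list of
    ``(ProjectedImage, BinaryMask, ClassifiedSegments)`` for audit.
    Deterministic for a fixed seed.
    """
    rois = sample_rois(volume, config, region=region, seed=seed)
    scores: list[LengthScore] = []
    artifacts = []
    for roi in rois:
        try:
            proj = sum_project(roi, config.slices_per_projection, config.slice_interval_um)
            score, bm, classified = score_projection(proj, config)
        except Exception as exc:
            raise RuntimeError(f"scoring failed for ROI {roi.index} "
                               f"(origin {roi.origin_um} um): {exc}") from exc
        scores.append(score)
        if keep_intermediates:
            artifacts.append((proj, bm, classified))
        log.debug("ROI %d: score=%.4f long=%d total=%d thr=%.1f",
                  roi.index, score.score, score.long_pixels, score.total_pixels,
                  score.threshold)
    valid = [s.score for s in scores if s.valid]
    log.info("scored %d ROIs: mean=%.4f (n_valid=%d)",
             len(scores), float(np.mean(valid)) if valid else float("nan"), len(valid))
    return (scores, artifacts) if keep_intermediates else scores


def time_course(scores_by_timepoint) -> TimeCourseTable:
    """Assemble per-timepoint scores into an ordered table with mean/sd/n.

    Accepts a mapping ``{day: [LengthScore, ...]}`` or an iterable of
    ``(day, scores)`` pairs; duplicate timepoint labels are an error.
    Invalid (no-foreground) scores are excluded from the summaries but
    preserved in the per-ROI table.
    """
    pairs = (list(scores_by_timepoint.items())
             if hasattr(scores_by_timepoint, "items")
             else [(float(d), s) for d, s in scores_by_timepoint])
    days = [d for d, _ in pairs]
    if len(set(days)) != len(days):
        raise ValueError(f"duplicate timepoint labels in {sorted(days)}")
    by_day = dict(pairs)
    rows = []
    for day in sorted(days):
        for s in by_day[day]:
            rows.append(dict(timepoint=day, roi_index=s.roi_index, score=s.score,
                             long_px=s.long_pixels, total_px=s.total_pixels,
                             threshold=s.threshold, valid=s.valid))
    per_roi = pd.DataFrame(rows)
    valid = per_roi[per_roi["valid"]]
    summary = (
        valid.groupby("timepoint")["score"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
        .sort_values("timepoint", ignore_index=True)
    )
    return TimeCourseTable(per_roi=per_roi, summary=summary)


def make_overlay(image: ProjectedImage, mask: BinaryMask,
                 classified: ClassifiedSegments,
                 connectivity: int = 8) -> np.ndarray:
    """RGB overlay: long segments green, short segments red, on the image.

    Mirrors the published long/short visualisation.
    """
    lab = cc_label(mask.mask, connectivity=1 if connectivity == 4 else 2)
    long_ids = {f.segment_id for f, l in zip(classified.features, classified.labels)
                if l == "long"}
    base = image.data.astype(np.float64)
    hi = np.percentile(base, 99.5) or 1.0
    gray = np.clip(base / hi * 255, 0, 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    is_long = np.isin(lab, sorted(long_ids)) & (lab > 0)
    is_short = (lab > 0) & ~is_long
    rgb[is_long] = [0, 200, 0]
    rgb[is_short] = [220, 0, 0]
    return rgb
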