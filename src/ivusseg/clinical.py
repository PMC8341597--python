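"""Clinical vessel quantities derived from a label mask.

Three clinically actionable readouts of a segmented IVUS cross-section:

* **lumen area** in mm^2 (pixel count times spacing squared) and the
  narrowed-lumen flag at the < 4 mm^2 threshold associated with elevated
  risk of major adverse cardiac events;
* **calcification arc** about the lumen centroid, its quadrant count over
  the four fixed 90-degree sectors, and the severe-calcification flag
  (arc in more than two quadrants);
* **stent struts** as connected components of the stent class, with a
  recall score against ground-truth strut positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing
from scipy.optimize import linear_sum_assignment
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from ivusseg.masks import CALCIFICATION, LUMEN, STENT, LabelMask


@dataclass
class ClinicalAssessment:
    """Clinically interpreted summary of one frame's mask."""

    lumen_area: float  # mm^2
    narrowed: bool  # lumen_area < 4.0 (strict)
    calc_arc_deg: float  # occupied 1-degree bins about the lumen centroid
    quadrant_count: int  # fixed 90-degree sectors containing calcification
    severe_calc: bool  # quadrant_count > 2
    strut_centroids: list[tuple[float, float]]  # (x, y) px


NARROWED_THRESHOLD_MM2 = 4.0
SEVERE_QUADRANTS = 2  # severe iff quadrant_count > this


def lumen_area(mask: LabelMask) -> float:
    """Lumen cross-sectional area in mm^2: pixel count times spacing squared."""
    if mask.pixel_spacing <= 0:
        raise ValueError("pixel spacing must be positive")
    return float(np.count_nonzero(mask.labels == LUMEN)) * mask.pixel_spacing**2


def classify_narrowed(area_mm2: float, threshold: float = NARROWED_THRESHOLD_MM2) -> bool:
    """Narrowed-lumen flag: strictly below the 4 mm^2 threshold."""
    if area_mm2 < 0:
        raise ValueError(f"lumen area must be non-negative, got {area_mm2}")
    return area_mm2 < threshold


def calcification_arc(
    mask: LabelMask,
    severe_rule: str = "quadrants",
) -> tuple[float, int, bool]:
    """Calcification arc (deg), quadrant count, and severity flag.

    Every calcification pixel's angle about the lumen centroid is binned
    into 1-degree bins; the arc is the number of occupied bins (summing
    occupied angle across disjoint deposits rather than taking a convex
    span).  Single-degree rasterization gaps in an otherwise solid arc are
    closed before counting.  The quadrant count is the number of the four
    fixed 90-degree sectors (anchored at the +x axis) containing at least
    one occupied bin; ``severe`` is true when calcification occupies more
    than two quadrants.

    ``severe_rule="arc180"`` switches to the alternative rule severe iff
    arc > 180 degrees.

    If calcification exists without any lumen pixels the image center is
    used as the angular reference (documented fallback).
    """
    if severe_rule not in ("quadrants", "arc180"):
        raise ValueError(f"unknown severe_rule {severe_rule!r}")
    ys, xs = np.nonzero(mask.labels == CALCIFICATION)
    if ys.size == 0:
        return 0.0, 0, False
    lys, lxs = np.nonzero(mask.labels == LUMEN)
    if lys.size:
        cy, cx = lys.mean(), lxs.mean()
    else:
        cy = cx = (mask.labels.shape[0] - 1) / 2.0
    theta = np.rad2deg(np.arctan2(ys - cy, xs - cx)) % 360.0
    bins = np.zeros(360, dtype=bool)
    bins[np.floor(theta).astype(int) % 360] = True
    # close 1-2 degree gaps left by rasterization at small radii; pad so the
    # closing wraps around the 0/360 seam
    k = 4
    padded = np.concatenate([bins[-k:], bins, bins[:k]])
    closed = binary_closing(padded, structure=np.ones(5, dtype=bool))[k : k + 360] | bins
    arc = float(np.count_nonzero(closed))
    quads = {q for q in range(4) if closed[90 * q : 90 * (q + 1)].any()}
    if severe_rule == "quadrants":
        severe = len(quads) > SEVERE_QUADRANTS
    else:
        severe = arc > 180.0
    return arc, len(quads), severe


def extract_struts(mask: LabelMask, min_pixels: int = 3) -> list[tuple[float, float]]:
    """Centroids (x, y) of stent-class connected components with >= min_pixels.

    8-connectivity, so diagonally touching blobs merge into one strut.
    """
    binary = mask.labels == STENT
    if not binary.any():
        return []
    lab = cc_label(binary, connectivity=2)
    out = []
    for rp in regionprops(lab):
        if rp.num_pixels >= min_pixels:
            cy, cx = rp.centroid
            out.append((float(cx), float(cy)))
    return out


def strut_recall(
    predicted: Sequence[tuple[float, float]],
    truth: Sequence[tuple[float, float]],
    tol_px: float = 5.0,
) -> float:
    """Fraction of true struts matched one-to-one by a prediction within tol_px.

    The matching maximizes the number of (pred, truth) pairs within the
    tolerance (optimal assignment, so no truth is sacrificed by a locally
    greedy pairing); among maximum matchings the one with the smallest total
    distance is chosen.  Returns 1.0 when there are no true struts.
    """
    if tol_px <= 0:
        raise ValueError("tol_px must be positive")
    if len(truth) == 0:
        return 1.0
    if len(predicted) == 0:
        return 0.0
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    d = np.hypot(p[:, None, 0] - t[None, :, 0], p[:, None, 1] - t[None, :, 1])
    big = d.max() + (tol_px + 1.0) * (d.shape[0] + d.shape[1] + 1)
    cost = np.where(d <= tol_px, d, big)
    ri, ci = linear_sum_assignment(cost)
    matched = int(np.count_nonzero(d[ri, ci] <= tol_px))
    return matched / len(truth)


def assess_mask(
    mask: LabelMask,
    min_strut_pixels: int = 3,
    severe_rule: str = "quadrants",
) -> ClinicalAssessment:
    """Full clinical assessment of one mask."""
    area = lumen_area(mask)
    arc, quads, severe = calcification_arc(mask, severe_rule=severe_rule)
    return ClinicalAssessment(
        lumen_area=area,
        narrowed=classify_narrowed(area),
        calc_arc_deg=arc,
        quadrant_count=quads,
        severe_calc=severe,
        strut_centroids=extract_struts(mask, min_pixels=min_strut_pixels),
    )


def clinical_report(
    frame_ids: Sequence[str],
    truth_masks: Sequence[LabelMask],
    pred_masks: Sequence[LabelMask],
    strut_tol_px: float = 5.0,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-frame clinical report comparing predicted masks with ground truth.

    One row per frame: predicted lumen area and flags, plus strut counts and
    the per-frame strut recall of predictions against the truth mask's
    struts.  Written as CSV when ``path`` is given.
    """
    rows = []
    for fid, tm, pm in zip(frame_ids, truth_masks, pred_masks):
        ta = assess_mask(tm)
        pa = assess_mask(pm)
        rows.append(
            {
                "frame_id": fid,
                "lumen_area_mm2": pa.lumen_area,
                "true_lumen_area_mm2": ta.lumen_area,
                "narrowed": pa.narrowed,
                "true_narrowed": ta.narrowed,
                "calc_arc_deg": pa.calc_arc_deg,
                "quadrant_count": pa.quadrant_count,
                "severe_calc": pa.severe_calc,
                "true_severe_calc": ta.severe_calc,
                "n_struts_true": len(ta.strut_centroids),
                "n_struts_pred": len(pa.strut_centroids),
                "strut_recall": strut_recall(pa.strut_centroids, ta.strut_centroids, tol_px=strut_tol_px),
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(Path(path), index=False)
    return df
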