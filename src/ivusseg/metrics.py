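"""Segmentation and image-level evaluation statistics.

Pixel metrics are computed from one-vs-rest confusion counts per class:

    IoU  = TP / (TP + FP + FN)
    Dice = 2 TP / (2 TP + FP + FN)
    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)

Means over classes are reported under two explicit aggregation modes,
``pooled`` (confusion counts summed over all images first) and
``macro_per_image`` (per-image metrics averaged first), because means of
overlap scores depend on the aggregation order and published reports rarely
state which was used.  Image-level classification (narrowed lumen, severe
calcification) reduces each frame pair to a flag and tallies a 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ivusseg.masks import CLASS_NAMES, N_CLASSES, LabelMask

_CONVENTION_ONE = 1.0  # value of 0/0 ratios: class absent in both masks


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest pixel confusion counts.

    For every class the four counts sum to the same total number of pixels
    evaluated.
    """

    tp: np.ndarray  # (n_classes,)
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass
class MetricsReport:
    """Per-class and mean IoU/Dice with an explicit aggregation-mode tag."""

    iou_per_class: dict[str, float]
    dice_per_class: dict[str, float]
    mean_iou: float
    mean_dice: float
    aggregation_mode: str
    n: int  # number of classes entering the means


@dataclass
class CorrelationReport:
    """Spearman rho, squared Pearson correlation and the rho p-value."""

    rho: float
    r_squared: float
    p_value: float


def confusion(pred: LabelMask, truth: LabelMask) -> ConfusionCounts:
    """One-vs-rest pixel confusion counts for each of the five classes."""
    if pred.labels.shape != truth.labels.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.labels.shape} vs truth {truth.labels.shape}"
        )
    p = pred.labels.ravel()
    t = truth.labels.ravel()
    # 5x5 contingency table: rows truth, cols pred
    table = np.bincount(t.astype(np.int64) * N_CLASSES + p, minlength=N_CLASSES * N_CLASSES)
    table = table.reshape(N_CLASSES, N_CLASSES)
    tp = np.diag(table).astype(np.int64)
    fn = table.sum(axis=1) - tp  # truth is c, predicted something else
    fp = table.sum(axis=0) - tp
    tn = table.sum() - tp - fn - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return _CONVENTION_ONE if den == 0 else float(num) / float(den)


def iou(tp: float, fp: float, fn: float) -> float:
    """Intersection over union; 1.0 when the class is absent from both masks."""
    return _ratio(tp, tp + fp + fn)


def dice(tp: float, fp: float, fn: float) -> float:
    """Dice score; 1.0 when the class is absent from both masks."""
    return _ratio(2 * tp, 2 * tp + fp + fn)


def accuracy(tp: float, fp: float, tn: float, fn: float) -> float:
    return _ratio(tp + tn, tp + fp + tn + fn)


def recall(tp: float, fn: float) -> float:
    """Sensitivity; 1.0 on an empty positive set (0/0)."""
    return _ratio(tp, tp + fn)


def precision(tp: float, fp: float) -> float:
    """Positive predictive value; 1.0 when nothing was predicted positive (0/0)."""
    return _ratio(tp, tp + fp)


def aggregate(
    pairs: Sequence[tuple[LabelMask, LabelMask]],
    mode: str = "pooled",
) -> MetricsReport:
    """Mean IoU/Dice over classes for a set of (pred, truth) mask pairs.

    ``pooled``: confusion counts are summed over all pairs before computing
    per-class metrics.  ``macro_per_image``: per-class metrics are computed
    per image and averaged over the images in which the class is present in
    the truth mask.  In both modes, classes absent from every truth mask
    are excluded from the means (so stent-free evaluation sets do not
    distort the mean with 0/0-convention ones).
    """
    if len(pairs) == 0:
        raise ValueError("aggregate requires at least one mask pair")
    if mode not in ("pooled", "macro_per_image"):
        raise ValueError(f"unknown aggregation mode {mode!r}")

    per_pair = [confusion(p, t) for p, t in pairs]
    truth_present = np.zeros(N_CLASSES, dtype=bool)
    for c in per_pair:
        truth_present |= (c.tp + c.fn) > 0

    iou_pc: dict[str, float] = {}
    dice_pc: dict[str, float] = {}
    if mode == "pooled":
        total = per_pair[0]
        for c in per_pair[1:]:
            total = total + c
        for k in range(N_CLASSES):
            iou_pc[CLASS_NAMES[k]] = iou(total.tp[k], total.fp[k], total.fn[k])
            dice_pc[CLASS_NAMES[k]] = dice(total.tp[k], total.fp[k], total.fn[k])
    else:
        for k in range(N_CLASSES):
            ious, dices = [], []
            for c in per_pair:
                if c.tp[k] + c.fn[k] > 0:  # class present in this truth mask
                    ious.append(iou(c.tp[k], c.fp[k], c.fn[k]))
                    dices.append(dice(c.tp[k], c.fp[k], c.fn[k]))
            if ious:
                iou_pc[CLASS_NAMES[k]] = float(np.mean(ious))
                dice_pc[CLASS_NAMES[k]] = float(np.mean(dices))
            else:
                iou_pc[CLASS_NAMES[k]] = _CONVENTION_ONE
                dice_pc[CLASS_NAMES[k]] = _CONVENTION_ONE

    avg_classes = [CLASS_NAMES[k] for k in range(N_CLASSES) if truth_present[k]]
    mean_iou = float(np.mean([iou_pc[c] for c in avg_classes]))
    mean_dice = float(np.mean([dice_pc[c] for c in avg_classes]))
    return MetricsReport(
        iou_per_class=iou_pc,
        dice_per_class=dice_pc,
        mean_iou=mean_iou,
        mean_dice=mean_dice,
        aggregation_mode=mode,
        n=len(avg_classes),
    )


def image_level_classification(
    frames: Sequence[tuple[LabelMask, LabelMask]],
    truth_rule: Callable[[LabelMask], bool],
    pred_rule: Callable[[LabelMask], bool] | None = None,
) -> tuple[float, float, float]:
    """Accuracy, recall and precision of a per-frame clinical flag.

    ``truth_rule`` maps a ground-truth mask to a boolean flag (e.g. narrowed
    lumen, severe calcification); ``pred_rule`` does the same for the
    predicted mask (defaults to ``truth_rule``).  The frames' flags are
    tallied into a 2x2 table.
    """
    if len(frames) == 0:
        raise ValueError("image-level classification requires at least one frame")
    pred_rule = truth_rule if pred_rule is None else pred_rule
    t = np.array([bool(truth_rule(tm)) for _, tm in frames])
    p = np.array([bool(pred_rule(pm)) for pm, _ in frames])
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return (
        accuracy(tp, fp, tn, fn),
        recall(tp, fn),
        precision(tp, fp),
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = stats.pearsonr(rx[list(perm)], ry)[0]
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def lumen_area_correlation(
    truth_areas: Sequence[float],
    predicted_areas: Sequence[float],
) -> CorrelationReport:
    """Agreement between predicted and ground-truth lumen areas.

    Spearman rank correlation (tie-corrected) with an exact permutation
    p-value for n <= 8 and the t-approximation above, plus the squared
    Pearson correlation as the coefficient of determination of the
    area-vs-area regression.
    """
    t = np.asarray(truth_areas, dtype=float)
    p = np.asarray(predicted_areas, dtype=float)
    if t.shape != p.shape:
        raise ValueError("area lists must have equal length")
    n = t.size
    if n < 3:
        raise ValueError(f"correlation needs n >= 3, got {n}")
    if np.ptp(t) == 0 or np.ptp(p) == 0:
        raise ValueError("correlation undefined for zero-variance inputs")
    rho, p_t = stats.spearmanr(t, p)
    if n <= 8:
        pval = _exact_spearman_p(t, p, rho)
    else:
        pval = float(p_t)
    r = stats.pearsonr(t, p)[0]
    return CorrelationReport(rho=float(rho), r_squared=float(r**2), p_value=pval)


def plot_area_agreement(
    truth_areas: Sequence[float],
    predicted_areas: Sequence[float],
    path: str | Path,
    report: CorrelationReport | None = None,
) -> None:
    """Scatter plot of predicted vs ground-truth lumen areas with identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.asarray(truth_areas, dtype=float)
    p = np.asarray(predicted_areas, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(t, p, s=14, alpha=0.7, edgecolors="none")
    lim = (0.0, float(max(t.max(), p.max())) * 1.05)
    ax.plot(lim, lim, "k--", lw=1, label="identity")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel("ground-truth lumen area (mm$^2$)")
    ax.set_ylabel("predicted lumen area (mm$^2$)")
    if report is not None:
        ax.set_title(f"$\\rho$ = {report.rho:.2f}, $R^2$ = {report.r_squared:.2f}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def report_to_frame(report: MetricsReport) -> pd.DataFrame:
    """Metrics report as a table: rows IoU/Dice, columns vessel classes."""
    cols = list(CLASS_NAMES)
    return pd.DataFrame(
        {
            c: [report.iou_per_class[c], report.dice_per_class[c]]
            for c in cols
        },
        index=["IoU", "Dice"],
    )


def write_report(report: MetricsReport, path: str | Path) -> None:
    """Write the metrics report as CSV with the aggregation-mode tag."""
    df = report_to_frame(report)
    df["mean"] = [report.mean_iou, report.mean_dice]
    df["mode"] = report.aggregation_mode
    df.to_csv(Path(path))
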