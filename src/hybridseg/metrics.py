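"""Segmentation evaluation: overlap metrics, pixel confusion statistics,
rank-based ROC-AUC, and percentile-bootstrap confidence intervals.

Two reporting modes coexist, matching common practice for segmentation
benchmarks: overlap scores (Dice, IoU, accuracy, F1) are computed per
image and then averaged (the bootstrap resamples images), while the
confusion matrix and one-vs-rest class statistics are pooled over every
pixel of a split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "ClasswiseReport",
    "MetricReport",
    "overlap_metrics",
    "confusion_and_classwise",
    "roc_auc",
    "bootstrap_ci",
    "report_from_scores",
]


@dataclass
class ConfusionCounts:
    """Pixel confusion matrix with foreground as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClasswiseReport:
    """One-vs-rest precision/recall/F1 for background and foreground."""

    counts: ConfusionCounts
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    weighted: dict[str, float]
    accuracy: float


@dataclass
class MetricReport:
    """Split-level summary: mean overlap scores with bootstrap CIs."""

    n_images: int
    point: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    per_image: dict[str, np.ndarray] = field(repr=False)
    classwise: ClasswiseReport | None = None
    auc: float | None = None

    def to_rows(self, split: str = "") -> list[dict]:
        rows = []
        for metric, value in self.point.items():
            rows.append(
                {
                    "split": split,
                    "metric": metric,
                    "point": value,
                    "ci_lower": self.ci_lower[metric],
                    "ci_upper": self.ci_upper[metric],
                }
            )
        if self.auc is not None:
            rows.append({"split": split, "metric": "auc", "point": self.auc,
                         "ci_lower": float("nan"), "ci_upper": float("nan")})
        return rows


def _as_binary(mask) -> np.ndarray:
    return (np.asarray(mask) > 0.5).astype(np.int64).ravel()


def overlap_metrics(pred, gt) -> dict[str, float]:
    """Hard-mask Dice, IoU, pixel accuracy, and foreground F1.

    By the both-empty convention, Dice and IoU of two empty masks are 1.
    On hard masks the foreground F1 coincides with Dice.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    p = _as_binary(pred)
    y = _as_binary(gt)
    inter = int((p & y).sum())
    psum, ysum = int(p.sum()), int(y.sum())
    union = psum + ysum - inter
    dice = 1.0 if psum + ysum == 0 else 2.0 * inter / (psum + ysum)
    iou = 1.0 if union == 0 else inter / union
    accuracy = float((p == y).mean())
    return {"dice": dice, "iou": iou, "accuracy": accuracy, "f1": dice}


def confusion_and_classwise(pred, gt) -> ClasswiseReport:
    """Pooled 2x2 pixel confusion matrix and one-vs-rest class statistics."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    p = _as_binary(pred)
    y = _as_binary(gt)
    tp = int(((p == 1) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)

    def prf(tp_, fp_, fn_):
        precision = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
        recall = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        return {"precision": precision, "recall": recall, "f1": f1}

    fg = prf(tp, fp, fn)
    bg = prf(tn, fn, fp)  # background positive: its FP are missed-foreground pixels
    support = {"background": tn + fp, "foreground": tp + fn}
    total = counts.total
    macro = {k: (bg[k] + fg[k]) / 2.0 for k in fg}
    weighted = {
        k: (bg[k] * support["background"] + fg[k] * support["foreground"]) / total
        for k in fg
    }
    return ClasswiseReport(
        counts=counts,
        per_class={"background": bg, "foreground": fg},
        macro=macro,
        weighted=weighted,
        accuracy=(tp + tn) / total,
    )


def roc_auc(
    scores,
    labels,
    max_pixels: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one half. ``max_pixels`` subsamples the
    inputs with the supplied generator for tractability on full-resolution
    splits; omit it for the exact value.
    """
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = _as_binary(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if max_pixels is not None and s.size > max_pixels:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(s.size, size=max_pixels, replace=False)
        s, y = s[idx], y[idx]
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_ci(
    per_image_scores: Sequence[float],
    resamples: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Percentile-bootstrap CI of the mean of per-image scores.

    Returns (lower, point, upper), where the point estimate is the sample
    mean and the bounds are the (1-level)/2 and 1-(1-level)/2 empirical
    quantiles of ``resamples`` resampled means. Deterministic given seed.
    """
    scores = np.asarray(per_image_scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("bootstrap_ci requires at least one score")
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = scores.size
    idx = rng.integers(0, n, size=(resamples, n))
    means = scores[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lower), float(scores.mean()), float(upper)


def report_from_scores(
    per_image: dict[str, np.ndarray],
    resamples: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    classwise: ClasswiseReport | None = None,
    auc: float | None = None,
) -> MetricReport:
    """Assemble a MetricReport from per-image score arrays."""
    point, lo, hi = {}, {}, {}
    for metric, values in per_image.items():
        l, m, u = bootstrap_ci(values, resamples=resamples, level=level, seed=seed)
        point[metric], lo[metric], hi[metric] = m, l, u
    n = len(next(iter(per_image.values())))
    return MetricReport(
        n_images=n, point=point, ci_lower=lo, ci_upper=hi,
        per_image=per_image, classwise=classwise, auc=auc,
    )
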