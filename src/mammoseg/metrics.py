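"""Segmentation overlap metrics (Dice, IoU, HD95), classification metrics
(accuracy, rank-based AUC) and the paired-classifier statistics: McNemar's
test on discordant counts and the chi-square goodness-of-fit test against
the ground-truth outcome distribution.

McNemar's statistic is (b - c)^2 / (b + c) with 1 degree of freedom,
*without* continuity correction by default; the Yates-corrected variant is
available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .io import LabelMask, validate_alignment

__all__ = [
    "PairedOutcomeTable",
    "GofInput",
    "dice_coefficient",
    "iou",
    "hd95",
    "accuracy",
    "auc",
    "mcnemar_chi2",
    "chisq_gof",
]


class MetricError(ValueError):
    """Metric undefined for the given inputs."""


def _mask_data(m) -> np.ndarray:
    return (m.data if isinstance(m, LabelMask) else np.asarray(m)) > 0


def _check_aligned(a, b) -> None:
    if isinstance(a, LabelMask) and isinstance(b, LabelMask):
        if not validate_alignment(a, b):
            raise MetricError("masks are not aligned (shape or spacing mismatch)")
    elif np.shape(a.data if isinstance(a, LabelMask) else a) != np.shape(
        b.data if isinstance(b, LabelMask) else b
    ):
        raise MetricError("masks have different shapes")


def dice_coefficient(a, b) -> float:
    """2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    _check_aligned(a, b)
    a, b = _mask_data(a), _mask_data(b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou(a, b) -> float:
    """|A n B| / |A u B|; 1.0 when both masks are empty."""
    _check_aligned(a, b)
    a, b = _mask_data(a), _mask_data(b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Surface voxels by 6-connected erosion difference."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def hd95(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of the pooled symmetric surface distances, in mm."""
    _check_aligned(a, b)
    if isinstance(a, LabelMask):
        spacing = a.spacing
    am, bm = _mask_data(a), _mask_data(b)
    if am.sum() == 0 or bm.sum() == 0:
        raise MetricError("HD95 requires two nonempty masks")
    sa, sb = _surface(am), _surface(bm)
    # distance-to-surface field for each mask, in physical mm
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    pooled = np.concatenate([dist_to_b[sa], dist_to_a[sb]])
    return float(np.percentile(pooled, 95))


def accuracy(labels, predictions) -> float:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise MetricError("labels and predictions must have equal length")
    return float((labels == predictions).mean())


def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise MetricError("labels and scores must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class PairedOutcomeTable:
    """2x2 agreement counts of two binary classifiers: a = both positive,
    b = only method 1 positive, c = only method 2 positive, d = both
    negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"count {name}={v!r} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_predictions(cls, pred1, pred2) -> "PairedOutcomeTable":
        p1 = np.asarray(pred1).astype(bool)
        p2 = np.asarray(pred2).astype(bool)
        if p1.shape != p2.shape:
            raise ValueError("prediction vectors must have equal length")
        return cls(
            a=int((p1 & p2).sum()),
            b=int((p1 & ~p2).sum()),
            c=int((~p1 & p2).sum()),
            d=int((~p1 & ~p2).sum()),
        )


def mcnemar_chi2(table: PairedOutcomeTable, correction: bool = False) -> tuple[float, float]:
    """McNemar's test on the discordant counts; returns (chi2, p)."""
    b, c = table.b, table.c
    if b + c == 0:
        raise MetricError("McNemar statistic undefined: no discordant pairs")
    if correction:
        chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        chi2 = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class GofInput:
    """Observed category counts vs ground-truth reference counts."""

    observed: np.ndarray
    expected_source: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.expected_source = np.asarray(self.expected_source, dtype=float)
        if self.observed.shape != self.expected_source.shape:
            raise ValueError("observed and reference must have the same categories")
        if (self.expected_source <= 0).any():
            raise MetricError("every expected category count must be positive")


def chisq_gof(inp: GofInput) -> tuple[float, float]:
    """Pearson goodness-of-fit of observed counts against the reference
    distribution scaled to the observed total; (categories - 1) df."""
    expected = inp.expected_source * inp.observed.sum() / inp.expected_source.sum()
    res = stats.chisquare(inp.observed, f_exp=expected)
    return float(res.statistic), float(res.pvalue)
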