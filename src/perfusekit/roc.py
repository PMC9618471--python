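"""ROC analysis for voxel-wise ischaemia classification.

A simple threshold classifier calls a voxel hypoperfused when its MTT
exceeds the threshold; sweeping the threshold over the observed MTT
values traces the ROC curve. The area under it (trapezoid rule, ties
contributing 1/2) equals the Mann-Whitney concordance probability.
Confidence intervals come from a percentile bootstrap over voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import Region, RegionLabelMap

__all__ = ["ROCCurve", "BootstrapCI", "make_truth_labels", "roc_curve",
           "bootstrap_auc_ci"]


@dataclass
class ROCCurve:
    """Threshold sweep of a 'score > threshold' classifier.

    ``thresholds`` descend from +inf; ``fpr``/``tpr`` are nondecreasing
    with endpoints (0, 0) and (1, 1). ``auc`` is the trapezoidal area.
    ``n_excluded`` counts NaN scores dropped before the sweep.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_excluded: int = 0


@dataclass
class BootstrapCI:
    """Percentile-bootstrap confidence interval for an AUC."""

    auc: float
    lower: float
    upper: float
    n_boot: int
    percentiles: tuple[float, float]
    seed: int | None
    n_redrawn: int = 0
    stratified: bool = False


def make_truth_labels(labels: RegionLabelMap) -> tuple[np.ndarray, np.ndarray]:
    """Binary ground truth from the phantom label map.

    Highly and moderately affected voxels are the positive (hypoperfused)
    class, unaffected voxels the negative class; background and blood
    pool are excluded.

    Returns
    -------
    y : int8 array over the selected voxels (1 positive, 0 negative)
    mask : boolean (z, y, x) array selecting those voxels, so that
        ``scores = mtt_map[mask]`` aligns with ``y``.
    """
    mask = labels.mask(Region.HIGHLY, Region.MODERATE, Region.UNAFFECTED)
    lab = labels.labels[mask]
    y = np.isin(lab, [int(Region.HIGHLY), int(Region.MODERATE)]).astype(np.int8)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(
            "both an affected and an unaffected class are required "
            f"(got {int(y.sum())} positives of {y.size})"
        )
    return y, mask


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve of the 'score > threshold' classifier.

    Sweeps thresholds over the unique score values (descending, with a
    leading +inf so the curve starts at (0, 0)); AUC by the trapezoid
    rule, which assigns tied positive/negative pairs weight 1/2.
    NaN scores are excluded and counted.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    keep = ~np.isnan(scores)
    n_excluded = int((~keep).sum())
    scores, labels = scores[keep], labels[keep]
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # indices where a tie group ends
    last_in_group = np.nonzero(np.diff(s))[0]
    idx = np.r_[last_in_group, s.size - 1]
    tps = np.cumsum(y)[idx]
    fps = (idx + 1) - tps
    tpr = np.concatenate(([0.0], tps / n_pos))
    fpr = np.concatenate(([0.0], fps / n_neg))
    thresholds = np.concatenate(([np.inf], s[idx]))
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
                    n_excluded=n_excluded)


def bootstrap_auc_ci(scores: np.ndarray, labels: np.ndarray,
                     n_boot: int = 1000,
                     percentiles: tuple[float, float] = (5.0, 95.0),
                     seed: int | None = None) -> BootstrapCI:
    """Percentile-bootstrap confidence interval for the ROC AUC.

    Voxels (score, label pairs) are resampled with replacement,
    unstratified; a replicate that loses one class entirely is redrawn
    so that exactly ``n_boot`` AUC replicates enter the percentiles.
    Fully seeded and reproducible.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    lo_pct, hi_pct = percentiles
    if not 0 <= lo_pct < hi_pct <= 100:
        raise ValueError("percentiles must satisfy 0 <= lo < hi <= 100")
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    point = roc_curve(scores, labels).auc  # validates both classes present

    rng = np.random.default_rng(seed)
    n = scores.size
    aucs = np.empty(n_boot)
    n_redrawn = 0
    max_consecutive = 10000
    for b in range(n_boot):
        for _attempt in range(max_consecutive):
            idx = rng.integers(0, n, n)
            yb = labels[idx]
            npos = int(yb.sum())
            if 0 < npos < n:
                break
            n_redrawn += 1
        else:
            raise RuntimeError(
                "bootstrap could not draw a replicate containing both classes"
            )
        aucs[b] = roc_curve(scores[idx], yb).auc
    lower, upper = np.percentile(aucs, [lo_pct, hi_pct])
    return BootstrapCI(auc=point, lower=float(lower), upper=float(upper),
                       n_boot=n_boot, percentiles=(lo_pct, hi_pct),
                       seed=seed, n_redrawn=n_redrawn, stratified=False)
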