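"""Segmentation overlap metrics: Jaccard, Dice and the paired error ratios.

With ground-truth foreground ``S_g``, model foreground ``S_m`` and their
overlap ``O``:

    JS  = |O| / |S_g u S_m|          DSC = 2 |O| / (|S_g| + |S_m|)
    RFP = |S_g \\ O| / |S_g|          RFN = |S_m \\ O| / |S_m|

RFP and RFN are implemented with exactly these denominators (|S_g| and
|S_m| respectively), which differ from conventional false-positive /
false-negative rates; under these definitions RFP measures the fraction
of ground truth left uncovered and RFN the fraction of the model mask
outside the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedMetricError


@dataclass(frozen=True)
class OverlapReport:
    js: float
    dsc: float
    rfp: float
    rfn: float
    n_gt: int
    n_seg: int
    n_overlap: int


def overlap_metrics(gt_mask, seg_mask) -> OverlapReport:
    """Overlap metrics between two same-shape, non-empty boolean masks."""
    gt = np.asarray(gt_mask, dtype=bool)
    seg = np.asarray(seg_mask, dtype=bool)
    if gt.shape != seg.shape:
        raise UndefinedMetricError(f"shape mismatch: {gt.shape} vs {seg.shape}")
    n_gt = int(gt.sum())
    n_seg = int(seg.sum())
    if n_gt == 0 or n_seg == 0:
        raise UndefinedMetricError("overlap metrics are undefined for empty masks")
    n_overlap = int(np.logical_and(gt, seg).sum())
    n_union = n_gt + n_seg - n_overlap
    return OverlapReport(
        js=n_overlap / n_union,
        dsc=2.0 * n_overlap / (n_gt + n_seg),
        rfp=(n_gt - n_overlap) / n_gt,
        rfn=(n_seg - n_overlap) / n_seg,
        n_gt=n_gt,
        n_seg=n_seg,
        n_overlap=n_overlap,
    )


def multiclass_metrics(gt_labels, seg_labels, class_id: int) -> OverlapReport:
    """Per-class overlap: binarize both label maps at ``class_id``."""
    gt = np.asarray(gt_labels)
    seg = np.asarray(seg_labels)
    if gt.shape != seg.shape:
        raise UndefinedMetricError(f"shape mismatch: {gt.shape} vs {seg.shape}")
    gt_mask = gt == class_id
    seg_mask = seg == class_id
    if not gt_mask.any():
        raise UndefinedMetricError(f"class {class_id} absent from ground truth")
    if not seg_mask.any():
        raise UndefinedMetricError(f"class {class_id} absent from segmentation")
    return overlap_metrics(gt_mask, seg_mask)


def best_match_dsc(gt_labels, seg_labels, classes) -> dict[int, float]:
    """Per-class DSC under the label permutation maximizing the mean DSC.

    Level-set class indices are arbitrary (they depend on seed placement),
    so quality against ground truth is evaluated after optimally matching
    segmentation labels to truth labels.
    """
    from itertools import permutations

    gt = np.asarray(gt_labels)
    seg = np.asarray(seg_labels)
    classes = list(classes)
    best: dict[int, float] | None = None
    best_mean = -1.0
    for perm in permutations(classes):
        scores = {}
        for gt_class, seg_class in zip(classes, perm):
            gt_mask = gt == gt_class
            seg_mask = seg == seg_class
            inter = int(np.logical_and(gt_mask, seg_mask).sum())
            denom = int(gt_mask.sum()) + int(seg_mask.sum())
            scores[gt_class] = 2.0 * inter / denom if denom else 0.0
        mean = sum(scores.values()) / len(scores)
        if mean > best_mean:
            best_mean = mean
            best = scores
    assert best is not None
    return best
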