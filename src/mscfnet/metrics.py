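"""Pixel- and instance-level evaluation for nucleus segmentation.

Implements the standard pixel overlap measures (Dice, IoU, pixel accuracy),
the Aggregated Jaccard Index (AJI) with a per-class variant computed
separately on marker-positive and marker-negative nuclei, an IHC
quantification difference based on the Ki-67 positivity index, and the
bridge from probability maps to instance label maps (thresholding +
connected components + small-object removal + aux-channel-based classing).

Conventions fixed here for reproducibility: empty-vs-empty masks score 1 for
Dice/IoU/AJI; an empty prediction against nonempty truth scores 0; AJI ties
between equal-IoU candidates resolve to the lowest predicted id, and each
predicted instance can be matched at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import sparse
from skimage.measure import label as cc_label

__all__ = ["InstanceLabelMap", "MetricsReport", "dice", "iou", "pixacc",
           "aji", "aji_per_class", "ihc_quant_diff", "instances_from_probs",
           "evaluate_pairs"]


@dataclass
class InstanceLabelMap:
    """Integer raster (0 = background, k > 0 = instance id) with optional
    per-instance class annotations ('positive' / 'negative')."""

    labels: np.ndarray
    classes: dict[int, str] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        if self.classes is not None:
            ids = set(np.unique(self.labels[self.labels > 0]).tolist())
            missing = ids - set(self.classes)
            if missing:
                raise ValueError(f"instances without class annotation: {sorted(missing)}")

    def restricted_to(self, cls: str) -> "InstanceLabelMap":
        """Keep only instances of one class; others become background."""
        if self.classes is None:
            raise ValueError("class restriction requires class annotations")
        keep = [i for i, c in self.classes.items() if c == cls]
        mask = np.isin(self.labels, keep)
        return InstanceLabelMap(np.where(mask, self.labels, 0),
                                {i: cls for i in keep})


@dataclass
class MetricsReport:
    pixacc: float
    dice: float
    iou: float
    aji: float
    aji_pos: float
    aji_neg: float
    ihc_quant_diff: float
    n_images: int

    def as_dict(self) -> dict:
        return asdict(self)


def _check_masks(pred, gt):
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return pred, gt


def dice(pred, gt) -> float:
    """2|P∩G| / (|P|+|G|); 1.0 when both masks are empty."""
    pred, gt = _check_masks(pred, gt)
    denom = pred.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, gt).sum() / denom)


def iou(pred, gt) -> float:
    """|P∩G| / |P∪G|; 1.0 when both masks are empty."""
    pred, gt = _check_masks(pred, gt)
    union = np.logical_or(pred, gt).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, gt).sum() / union)


def pixacc(pred, gt) -> float:
    pred, gt = _check_masks(pred, gt)
    return float((pred == gt).mean())


def _contingency(pred: np.ndarray, gt: np.ndarray):
    """Sparse pairwise pixel-overlap table between gt and pred instances."""
    mask = (pred > 0) | (gt > 0)
    g = gt[mask].ravel().astype(np.int64)
    p = pred[mask].ravel().astype(np.int64)
    ng, np_ = int(gt.max()) + 1, int(pred.max()) + 1
    table = sparse.coo_matrix((np.ones(g.size, dtype=np.int64), (g, p)),
                              shape=(ng, np_)).tocsr()
    return table


def aji(pred: InstanceLabelMap | np.ndarray, gt: InstanceLabelMap | np.ndarray) -> float:
    """Aggregated Jaccard Index.

    For each ground-truth instance (ascending id) the still-unmatched
    predicted instance with the highest pairwise IoU is matched (ties ->
    lowest predicted id); matched intersections/unions accumulate, and the
    areas of unmatched predicted instances are added to the pooled union.
    """
    pl = pred.labels if isinstance(pred, InstanceLabelMap) else np.asarray(pred)
    gl = gt.labels if isinstance(gt, InstanceLabelMap) else np.asarray(gt)
    if pl.shape != gl.shape:
        raise ValueError(f"shape mismatch: {pl.shape} vs {gl.shape}")
    gt_ids = np.unique(gl[gl > 0])
    pred_ids = np.unique(pl[pl > 0])
    if gt_ids.size == 0:
        return 1.0 if pred_ids.size == 0 else 0.0
    if pred_ids.size == 0:
        return 0.0

    table = _contingency(pl, gl)
    pred_areas = {int(j): int(np.sum(pl == j)) for j in pred_ids}
    gt_areas = {int(i): int(np.sum(gl == i)) for i in gt_ids}
    used: set[int] = set()
    inter_total = 0
    union_total = 0
    for i in gt_ids:
        i = int(i)
        row = table.getrow(i)
        best_j, best_iou, best_inter = None, -1.0, 0
        for j, inter in sorted(zip(row.indices.tolist(), row.data.tolist())):
            if j == 0 or j in used or inter == 0:
                continue
            u = gt_areas[i] + pred_areas[j] - inter
            pair_iou = inter / u
            if pair_iou > best_iou:  # strict: ties keep the lowest id seen first
                best_j, best_iou, best_inter = j, pair_iou, int(inter)
        if best_j is None:
            union_total += gt_areas[i]
        else:
            used.add(best_j)
            inter_total += best_inter
            union_total += gt_areas[i] + pred_areas[best_j] - best_inter
    for j in pred_ids:
        if int(j) not in used:
            union_total += pred_areas[int(j)]
    return float(inter_total / union_total) if union_total else 1.0


def aji_per_class(pred: InstanceLabelMap, gt: InstanceLabelMap) -> tuple[float, float]:
    """AJI restricted to marker-positive and to marker-negative instances."""
    if pred.classes is None or gt.classes is None:
        raise ValueError("per-class AJI requires class annotations on both maps")
    a_pos = aji(pred.restricted_to("positive"), gt.restricted_to("positive"))
    a_neg = aji(pred.restricted_to("negative"), gt.restricted_to("negative"))
    return a_pos, a_neg


def _positivity_index(m: InstanceLabelMap) -> float:
    if m.classes is None:
        raise ValueError("positivity index requires class annotations")
    ids = np.unique(m.labels[m.labels > 0])
    if ids.size == 0:
        return 0.0
    n_pos = sum(1 for i in ids if m.classes[int(i)] == "positive")
    return n_pos / ids.size


def ihc_quant_diff(pred: InstanceLabelMap, gt: InstanceLabelMap) -> float:
    """Absolute difference of Ki-67 positivity indices (fraction of
    marker-positive instances); prediction with no instances counts as 0."""
    gt_ids = np.unique(gt.labels[gt.labels > 0])
    if gt_ids.size == 0:
        raise ValueError("ground truth must contain at least one instance")
    return abs(_positivity_index(pred) - _positivity_index(gt))


def default_min_size(tile_size: int) -> int:
    """Small-object cutoff: 10 px at 64-px tiles, scaled quadratically."""
    return max(1, int(round(10 * (tile_size / 64.0) ** 2)))


def instances_from_probs(seg_probs: np.ndarray, aux_pred: np.ndarray | None = None,
                         threshold: float = 0.5, min_size: int | None = 10,
                         connectivity: int = 8) -> InstanceLabelMap:
    """Binary foreground probability -> instance label map.

    seg_probs: (K, H, W) per-pixel class distribution (class 1 = nucleus) or
        an (H, W) foreground probability.
    aux_pred: optional (2, H, W) predicted marker channels used to class each
        instance (mean aux_pos vs mean aux_neg over its pixels; tie -> negative).
    """
    seg_probs = np.asarray(seg_probs)
    fg_prob = seg_probs if seg_probs.ndim == 2 else seg_probs[1]
    if min_size is None:
        min_size = default_min_size(max(fg_prob.shape))
    fg = fg_prob >= threshold
    conn = {4: 1, 8: 2}[connectivity]
    labels = cc_label(fg, connectivity=conn).astype(np.int32)
    # drop small components, then relabel contiguously
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    small = ids[counts < min_size]
    if small.size:
        labels[np.isin(labels, small)] = 0
    remap = {int(old): new for new, old in enumerate(np.unique(labels[labels > 0]), 1)}
    out = np.zeros_like(labels)
    for old, new in remap.items():
        out[labels == old] = new
    classes: dict[int, str] | None = None
    if aux_pred is not None:
        aux_pred = np.asarray(aux_pred)
        classes = {}
        for i in remap.values():
            m = out == i
            classes[i] = ("positive"
                          if aux_pred[0][m].mean() > aux_pred[1][m].mean()
                          else "negative")
    return InstanceLabelMap(out, classes)


def evaluate_pairs(preds: list[InstanceLabelMap], gts: list[InstanceLabelMap]) -> MetricsReport:
    """Per-image metrics averaged over a list of (prediction, truth) pairs."""
    if len(preds) != len(gts) or not preds:
        raise ValueError("need equally many predictions and ground truths (>= 1)")
    rows = []
    for p, g in zip(preds, gts):
        pm, gm = p.labels > 0, g.labels > 0
        has_classes = p.classes is not None and g.classes is not None
        a_pos, a_neg = aji_per_class(p, g) if has_classes else (np.nan, np.nan)
        qd = ihc_quant_diff(p, g) if has_classes and (g.labels > 0).any() else np.nan
        rows.append((pixacc(pm, gm), dice(pm, gm), iou(pm, gm), aji(p, g),
                     a_pos, a_neg, qd))
    mean = np.nanmean(np.asarray(rows, dtype=float), axis=0)
    return MetricsReport(*[float(v) for v in mean], n_images=len(preds))
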