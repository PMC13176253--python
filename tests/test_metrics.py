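"""Metric suite: worked micro-values, empty-case conventions, and exact
agreement of the fast AJI with an exhaustive brute-force reference."""

import numpy as np
import pytest

from mscfnet.metrics import (InstanceLabelMap, aji, aji_per_class, dice,
                             evaluate_pairs, ihc_quant_diff,
                             instances_from_probs, iou, pixacc)

from conftest import random_instance_map


# -- brute-force references ---------------------------------------------------

def aji_reference(pred: np.ndarray, gt: np.ndarray) -> float:
    """O(n_pred * n_gt) exhaustive re-statement of the matching rule: per gt
    instance (ascending id), the unused predicted instance with max IoU,
    ties to the lowest predicted id; unmatched predictions join the union."""
    gt_ids = [int(i) for i in np.unique(gt[gt > 0])]
    pred_ids = [int(j) for j in np.unique(pred[pred > 0])]
    if not gt_ids:
        return 1.0 if not pred_ids else 0.0
    if not pred_ids:
        return 0.0
    used = set()
    inter_sum = union_sum = 0
    for i in gt_ids:
        gm = gt == i
        best = None
        for j in pred_ids:
            if j in used:
                continue
            pm = pred == j
            inter = int((gm & pm).sum())
            if inter == 0:
                continue
            pair_iou = inter / int((gm | pm).sum())
            if best is None or pair_iou > best[0]:
                best = (pair_iou, j, inter, int((gm | pm).sum()))
        if best is None:
            union_sum += int(gm.sum())
        else:
            _, j, inter, union = best
            used.add(j)
            inter_sum += inter
            union_sum += union
    for j in pred_ids:
        if j not in used:
            union_sum += int((pred == j).sum())
    return inter_sum / union_sum


# -- pixel metrics ------------------------------------------------------------

def test_pixel_metrics_worked_values():
    # 2x2 grid with TP=2, FP=1, FN=1
    pred = np.array([[1, 1], [1, 0]], bool)
    gt = np.array([[1, 1], [0, 1]], bool)
    assert dice(pred, gt) == pytest.approx(2 * 2 / (2 * 2 + 1 + 1), abs=1e-12)
    assert iou(pred, gt) == pytest.approx(0.5, abs=1e-12)
    assert pixacc(pred, gt) == pytest.approx(0.5, abs=1e-12)


@pytest.mark.parametrize("a,b,d,i", [
    (np.ones((3, 3), bool), np.ones((3, 3), bool), 1.0, 1.0),
    (np.zeros((3, 3), bool), np.zeros((3, 3), bool), 1.0, 1.0),
    (np.eye(3, dtype=bool), ~np.eye(3, dtype=bool), 0.0, 0.0),
])
def test_pixel_metrics_edge_conventions(a, b, d, i):
    assert dice(a, b) == d
    assert iou(a, b) == i


def test_pixel_metrics_match_count_oracle(rng):
    for _ in range(500):
        p = rng.random((8, 8)) > 0.5
        g = rng.random((8, 8)) > 0.5
        tp = int((p & g).sum())
        fp = int((p & ~g).sum())
        fn = int((~p & g).sum())
        if tp + fp + fn:
            assert dice(p, g) == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)
            assert iou(p, g) == pytest.approx(tp / (tp + fp + fn), abs=1e-12)
        assert pixacc(p, g) == pytest.approx(1 - (fp + fn) / 64, abs=1e-12)


def test_dice_iou_identity(rng):
    for _ in range(500):
        p = rng.random((10, 10)) > rng.random()
        g = rng.random((10, 10)) > rng.random()
        j = iou(p, g)
        assert dice(p, g) == pytest.approx(2 * j / (1 + j), abs=1e-9)


def test_shape_mismatch_raises():
    with pytest.raises(ValueError):
        dice(np.ones((2, 2), bool), np.ones((3, 3), bool))
    with pytest.raises(ValueError):
        aji(np.ones((2, 2), np.int32), np.ones((3, 2), np.int32))


# -- AJI ----------------------------------------------------------------------

def test_aji_perfect_and_empty():
    m = np.array([[1, 1, 0], [0, 2, 2], [0, 0, 0]], np.int32)
    assert aji(m, m) == 1.0
    assert aji(np.zeros_like(m), m) == 0.0
    assert aji(np.zeros_like(m), np.zeros_like(m)) == 1.0
    assert aji(m, np.zeros_like(m)) == 0.0


def test_aji_toy_matches_hand_enumeration():
    # 4x4: 2 gt instances, 3 predicted; follow the matching rule by hand
    gt = np.array([[1, 1, 0, 0],
                   [1, 1, 0, 0],
                   [0, 0, 2, 2],
                   [0, 0, 2, 2]], np.int32)
    pred = np.array([[1, 1, 0, 0],
                     [1, 0, 0, 0],
                     [0, 0, 2, 0],
                     [3, 3, 2, 2]], np.int32)
    # gt1: only pred1 overlaps (inter 3, union 4, iou .75) -> match (3, 4)
    # gt2: pred2 overlaps (inter 3, union 4, iou .75)      -> match (3, 4)
    # pred3 unmatched -> union += 2
    expected = (3 + 3) / (4 + 4 + 2)
    assert aji(pred, gt) == pytest.approx(expected, abs=1e-12)
    assert aji_reference(pred, gt) == pytest.approx(expected, abs=1e-12)


def test_aji_equals_bruteforce_on_random_maps(rng):
    """Exact oracle equivalence on 200 random 16x16 instance maps."""
    for _ in range(200):
        gt, _ = random_instance_map(rng, (16, 16), n_blobs=int(rng.integers(0, 6)))
        pred, _ = random_instance_map(rng, (16, 16), n_blobs=int(rng.integers(0, 6)))
        assert aji(pred, gt) == pytest.approx(aji_reference(pred, gt), abs=0)


def test_aji_one_iff_identical_partition(rng):
    for _ in range(50):
        gt, _ = random_instance_map(rng, (12, 12), n_blobs=3)
        assert aji(gt, gt) == 1.0
        # any relabeling of ids is still the same partition
        perm = gt.copy()
        perm[gt == 1], perm[gt == 2] = 2, 1
        if len(np.unique(gt[gt > 0])) >= 2:
            assert aji(perm, gt) == 1.0
        # merging two instances changes the partition -> strictly below 1
        merged = np.where(gt > 0, 1, 0).astype(np.int32)
        if len(np.unique(gt[gt > 0])) >= 2:
            assert aji(merged, gt) < 1.0


# -- per-class AJI and positivity difference ----------------------------------

def test_aji_per_class_all_positive_and_swapped():
    m = np.array([[1, 0], [0, 2]], np.int32)
    pos = InstanceLabelMap(m, {1: "positive", 2: "positive"})
    assert aji_per_class(pos, pos) == (1.0, 1.0)   # neg side: empty vs empty
    swapped = InstanceLabelMap(m, {1: "negative", 2: "negative"})
    a_pos, a_neg = aji_per_class(swapped, pos)
    assert a_pos == 0.0 and a_neg == 0.0           # disjoint supports per class


def test_aji_per_class_matches_restricted_bruteforce(rng):
    for _ in range(30):
        gt, gc = random_instance_map(rng, (16, 16), n_blobs=4, with_classes=True)
        pred, pc = random_instance_map(rng, (16, 16), n_blobs=4, with_classes=True)
        pm, gm = InstanceLabelMap(pred, pc), InstanceLabelMap(gt, gc)
        a_pos, a_neg = aji_per_class(pm, gm)
        for val, cls in ((a_pos, "positive"), (a_neg, "negative")):
            ref = aji_reference(pm.restricted_to(cls).labels,
                                gm.restricted_to(cls).labels)
            assert val == pytest.approx(ref, abs=0)


def test_ihc_quant_diff_worked_and_oracle(rng):
    m = np.array([[1, 2], [3, 4]], np.int32)
    gt = InstanceLabelMap(m, {1: "positive", 2: "positive", 3: "negative", 4: "negative"})
    pred = InstanceLabelMap(m, {1: "positive", 2: "negative", 3: "negative", 4: "negative"})
    assert ihc_quant_diff(gt, gt) == 0.0
    assert ihc_quant_diff(pred, gt) == pytest.approx(0.25, abs=1e-12)
    for _ in range(30):
        g, gc = random_instance_map(rng, (12, 12), n_blobs=3, with_classes=True)
        p, pc = random_instance_map(rng, (12, 12), n_blobs=3, with_classes=True)
        if not (g > 0).any():
            continue
        gm, pm = InstanceLabelMap(g, gc), InstanceLabelMap(p, pc)
        def index(m_):
            ids = np.unique(m_.labels[m_.labels > 0])
            return (sum(m_.classes[int(i)] == "positive" for i in ids) / ids.size
                    if ids.size else 0.0)
        assert ihc_quant_diff(pm, gm) == pytest.approx(abs(index(pm) - index(gm)), abs=1e-12)


def test_ihc_quant_diff_empty_pred_counts_as_zero_index():
    m = np.array([[1, 0], [0, 2]], np.int32)
    gt = InstanceLabelMap(m, {1: "positive", 2: "negative"})
    empty = InstanceLabelMap(np.zeros_like(m), {})
    assert ihc_quant_diff(empty, gt) == pytest.approx(0.5)


# -- instance extraction ------------------------------------------------------

def test_instances_from_probs_connectivity_and_small_removal():
    fg = np.zeros((6, 6), np.float32)
    fg[0:2, 0:2] = 1.0            # blob A
    fg[2, 2] = 1.0                # touches A only diagonally
    m8 = instances_from_probs(fg, threshold=0.5, min_size=1, connectivity=8)
    m4 = instances_from_probs(fg, threshold=0.5, min_size=1, connectivity=4)
    assert len(np.unique(m8.labels[m8.labels > 0])) == 1
    assert len(np.unique(m4.labels[m4.labels > 0])) == 2
    # min_size removes the single-pixel component
    m4s = instances_from_probs(fg, threshold=0.5, min_size=2, connectivity=4)
    assert len(np.unique(m4s.labels[m4s.labels > 0])) == 1


def test_instances_from_probs_empty_and_classing():
    assert instances_from_probs(np.zeros((4, 4), np.float32)).labels.max() == 0
    fg = np.zeros((4, 4), np.float32)
    fg[0:2, 0:2] = 0.9
    aux = np.zeros((2, 4, 4), np.float32)
    aux[0, 0:2, 0:2] = 0.8        # positive channel brighter
    m = instances_from_probs(fg, aux, min_size=1)
    assert m.classes == {1: "positive"}
    aux_tie = np.zeros((2, 4, 4), np.float32)
    m2 = instances_from_probs(fg, aux_tie, min_size=1)
    assert m2.classes == {1: "negative"}   # ties resolve to negative


def test_evaluate_pairs_aggregates():
    m = np.array([[1, 0], [0, 2]], np.int32)
    im = InstanceLabelMap(m, {1: "positive", 2: "negative"})
    rep = evaluate_pairs([im, im], [im, im])
    assert rep.n_images == 2
    assert rep.dice == rep.iou == rep.pixacc == rep.aji == 1.0
    assert rep.ihc_quant_diff == 0.0


# -- property tests -----------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


@settings(max_examples=60, derandomize=True, deadline=None)
@given(arrays(bool, (9, 9), elements=st.booleans()),
       arrays(bool, (9, 9), elements=st.booleans()))
def test_dice_iou_identity_and_bounds_property(p, g):
    j = iou(p, g)
    assert dice(p, g) == pytest.approx(2 * j / (1 + j), abs=1e-9)
    assert 0.0 <= j <= 1.0
    # pixacc = 1 - |symmetric difference| / area, by definition
    assert pixacc(p, g) == pytest.approx(1 - np.logical_xor(p, g).mean(), abs=1e-12)
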