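"""Anchor matching and loss-function tests with closed-form oracles."""

import math

import numpy as np
import pytest

from grainseg import tensor as T
from grainseg.losses import (
    box_loss,
    classification_loss,
    mask_loss,
    match_anchors,
    smooth_l1,
    total_loss,
)
from grainseg.tensor import Tensor

RNG = np.random.default_rng(41)


# ---------------------------------------------------------------------------
# smooth L1
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,expect", [(0.0, 0.0), (1.0, 0.5), (2.0, 1.5),
                                      (-1.0, 0.5), (-3.0, 2.5), (0.5, 0.125)])
def test_smooth_l1_values(x, expect):
    assert abs(smooth_l1(x) - expect) < 1e-9


def test_smooth_l1_continuous_and_once_differentiable_at_one():
    eps = 1e-6
    assert abs(smooth_l1(1 - eps) - smooth_l1(1 + eps)) < 1e-5
    # gradient approaches 1 from both sides of |x| = 1
    g_in = (smooth_l1(1 - eps) - smooth_l1(1 - 3 * eps)) / (2 * eps)
    g_out = (smooth_l1(1 + 3 * eps) - smooth_l1(1 + eps)) / (2 * eps)
    assert abs(g_in - 1.0) < 1e-3 and abs(g_out - 1.0) < 1e-3


def test_smooth_l1_gradient_bounded_by_one():
    x = Tensor(np.array([-5.0, -0.5, 0.5, 5.0], np.float32), requires_grad=True)
    T.smooth_l1(x).sum().backward()
    assert np.all(np.abs(x.grad) <= 1.0 + 1e-6)
    assert np.allclose(x.grad, [-1.0, -0.5, 0.5, 1.0])


# ---------------------------------------------------------------------------
# anchor matching
# ---------------------------------------------------------------------------

def _cs(x1, y1, x2, y2):
    return [(x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1]


def test_identical_anchor_is_positive():
    m = match_anchors(np.array([_cs(10, 10, 20, 20)]),
                      np.array([[10.0, 10, 20, 20]]), np.array([3]))
    assert m.labels.tolist() == [4] and m.matched.tolist() == [0]


def test_no_truths_all_negative():
    m = match_anchors(np.array([_cs(0, 0, 5, 5)]), np.zeros((0, 4)),
                      np.zeros(0, np.int64))
    assert m.labels.tolist() == [0] and m.positives.size == 0


def test_hand_computed_iou_table_labels():
    """3 anchors vs 2 truths with hand-checked IoUs.

    anchor0 == truth0 (IoU 1 -> positive, class 1); anchor1 far away
    (IoU 0 -> negative); anchor2 overlaps truth1 at IoU 9/23 ~ 0.39
    (< 0.4 -> negative) but is truth1's best anchor -> force-matched.
    """
    anchors = np.array([
        _cs(0, 0, 10, 10),
        _cs(50, 50, 60, 60),
        _cs(20, 20, 28, 28),
    ])
    truths = np.array([[0.0, 0, 10, 10], [22.0, 22, 30, 30]])
    iou_02 = 36.0 / (64 + 64 - 36)  # hand: 6x6 overlap of two 8x8 boxes
    assert abs(iou_02 - 9 / 23) < 1e-9
    m = match_anchors(anchors, truths, np.array([0, 4]))
    assert m.labels.tolist() == [1, 0, 5]
    assert m.matched.tolist() == [0, -1, 1]


# ---------------------------------------------------------------------------
# box loss
# ---------------------------------------------------------------------------

def _single_positive_match():
    anchors = np.array([_cs(0, 0, 10, 10), _cs(40, 40, 50, 50)])
    truths = np.array([[0.0, 0, 10, 10]])
    return anchors, truths, match_anchors(anchors, truths, np.array([0]))


def test_box_loss_zero_for_perfect_regression():
    anchors, truths, m = _single_positive_match()
    from grainseg.assembly import encode_boxes

    deltas = np.zeros((2, 4), np.float32)
    deltas[0] = encode_boxes(truths, anchors[:1])
    assert float(box_loss(Tensor(deltas), m, anchors, truths).data) < 1e-10


def test_box_loss_unit_residual_gives_half():
    anchors, truths, m = _single_positive_match()
    from grainseg.assembly import encode_boxes

    deltas = np.zeros((2, 4), np.float32)
    deltas[0] = encode_boxes(truths, anchors[:1])
    deltas[0, 0] += 1.0  # residual (1, 0, 0, 0) on the one positive
    assert abs(float(box_loss(Tensor(deltas), m, anchors, truths).data) - 0.5) < 1e-6


def test_box_loss_invariant_to_anchor_order():
    anchors = np.array([_cs(0, 0, 10, 10), _cs(20, 0, 30, 10)])
    truths = np.array([[0.0, 0, 10, 10], [20.0, 0, 30, 10]])
    labels = np.array([0, 1])
    deltas = RNG.standard_normal((2, 4)).astype(np.float32)
    l1 = box_loss(Tensor(deltas), match_anchors(anchors, truths, labels),
                  anchors, truths)
    perm = [1, 0]
    l2 = box_loss(Tensor(deltas[perm]),
                  match_anchors(anchors[perm], truths, labels),
                  anchors[perm], truths)
    assert np.isclose(float(l1.data), float(l2.data), atol=1e-6)


# ---------------------------------------------------------------------------
# classification loss
# ---------------------------------------------------------------------------

def test_saturated_correct_logits_drive_loss_to_zero():
    anchors, truths, m = _single_positive_match()
    logits = np.zeros((2, 3), np.float32)
    logits[0, 1] = 50.0  # positive anchor, class 1 (= label index 1)
    logits[1, 0] = 50.0  # negative anchor confident background
    assert float(classification_loss(Tensor(logits), m).data) < 1e-6


def test_uniform_logits_give_log_c_plus_one():
    anchors, truths, m = _single_positive_match()
    logits = np.zeros((2, 9), np.float32)  # c+1 = 9 uniform classes
    loss = classification_loss(Tensor(logits), m)
    assert abs(float(loss.data) - math.log(9)) < 1e-6


def test_hard_negative_cap_three_to_one():
    """With 2 positives and many negatives, at most 6 negatives receive
    gradient (participation ratio never exceeds 3:1)."""
    n = 40
    anchors = [_cs(0, 0, 10, 10), _cs(20, 0, 30, 10)]
    anchors += [_cs(100 + 11 * i, 100, 108 + 11 * i, 108) for i in range(n - 2)]
    anchors = np.array(anchors)
    truths = np.array([[0.0, 0, 10, 10], [20.0, 0, 30, 10]])
    m = match_anchors(anchors, truths, np.array([0, 1]))
    assert m.positives.size == 2
    logits = Tensor(RNG.standard_normal((n, 3)).astype(np.float32),
                    requires_grad=True)
    classification_loss(logits, m).backward()
    touched = np.flatnonzero(np.abs(logits.grad).sum(axis=1) > 0)
    n_neg = np.setdiff1d(touched, m.positives).size
    assert n_neg <= 3 * m.positives.size
    assert n_neg == 6


# ---------------------------------------------------------------------------
# mask loss
# ---------------------------------------------------------------------------

def _mask_setup(H=16):
    anchors = np.array([_cs(2, 2, 10, 10)])
    truths = np.array([[2.0, 2, 10, 10]])
    gt_mask = np.zeros((1, H, H), bool)
    gt_mask[0, 4:8, 4:8] = True  # aligned with the 2x downsampling grid
    m = match_anchors(anchors, truths, np.array([0]))
    return anchors, truths, gt_mask, m


def test_mask_loss_zero_when_assembled_equals_truth():
    _, truths, gt_mask, m = _mask_setup()
    # one prototype: +-25 logits reproducing the truth at prototype scale
    small = gt_mask[0].reshape(8, 2, 8, 2).mean(axis=(1, 3)) > 0.5
    protos = np.where(small, 25.0, -25.0).astype(np.float32)[None]
    coef = np.ones((1, 1), np.float32)
    loss = mask_loss(Tensor(protos), Tensor(coef), m, gt_mask, truths)
    assert float(loss.data) < 1e-6


def test_mask_loss_uniform_half_is_ln2_per_pixel():
    _, truths, gt_mask, m = _mask_setup()
    protos = np.zeros((1, 8, 8), np.float32)
    coef = np.zeros((1, 1), np.float32)
    loss = mask_loss(Tensor(protos), Tensor(coef), m, gt_mask, truths)
    assert abs(float(loss.data) - math.log(2)) < 1e-5


def test_mask_loss_flip_symmetry():
    anchors = np.array([_cs(2, 2, 10, 10)])
    H = 16
    truths = np.array([[2.0, 2, 10, 10]])
    gt = np.zeros((1, H, H), bool)
    gt[0, 3:9, 3:7] = True
    m = match_anchors(anchors, truths, np.array([0]))
    protos = RNG.standard_normal((2, 8, 8)).astype(np.float32)
    coef = RNG.standard_normal((1, 2)).astype(np.float32)
    l1 = mask_loss(Tensor(protos), Tensor(coef), m, gt, truths)
    # mirror everything horizontally (truth box is x-symmetric on the canvas)
    gt_f = gt[:, :, ::-1]
    box_f = np.array([[H - truths[0, 2], truths[0, 1], H - truths[0, 0], truths[0, 3]]])
    protos_f = protos[:, :, ::-1].copy()
    l2 = mask_loss(Tensor(protos_f), Tensor(coef), m, gt_f, box_f)
    assert np.isclose(float(l1.data), float(l2.data), atol=1e-5)


def test_mask_loss_skips_degenerate_truth_box():
    anchors = np.array([_cs(2, 2, 10, 10)])
    truths = np.array([[5.0, 5, 5, 5]])  # zero area
    gt = np.zeros((1, 16, 16), bool)
    m = match_anchors(anchors, truths, np.array([0]))
    m.labels[0], m.matched[0] = 1, 0  # force the degenerate match
    with pytest.warns(UserWarning):
        loss = mask_loss(Tensor(np.zeros((1, 8, 8), np.float32)),
                         Tensor(np.zeros((1, 1), np.float32)), m, gt, truths)
    assert float(loss.data) == 0.0


# ---------------------------------------------------------------------------
# total loss
# ---------------------------------------------------------------------------

def test_total_loss_composition():
    from grainseg.config import LossConfig

    assert float(total_loss(0.0, 0.0, 0.0).data) == 0.0
    only_cls = LossConfig(cls_weight=1.0, box_weight=0.0, mask_weight=0.0)
    assert float(total_loss(2.5, 9.0, 9.0, only_cls).data) == 2.5
    # linearity in each component, checked at two points
    cfg = LossConfig()
    base = float(total_loss(1.0, 1.0, 1.0, cfg).data)
    assert np.isclose(float(total_loss(2.0, 1.0, 1.0, cfg).data) - base,
                      cfg.cls_weight, atol=1e-6)
    assert np.isclose(float(total_loss(1.0, 3.0, 1.0, cfg).data) - base,
                      2 * cfg.box_weight, atol=1e-6)
    assert np.isclose(float(total_loss(1.0, 1.0, 2.0, cfg).data) - base,
                      cfg.mask_weight, atol=1e-5)


def test_losses_nonnegative_and_finite():
    anchors, truths, m = _single_positive_match()
    logits = RNG.standard_normal((2, 5)).astype(np.float32) * 10
    deltas = RNG.standard_normal((2, 4)).astype(np.float32) * 10
    lc = float(classification_loss(Tensor(logits), m).data)
    lb = float(box_loss(Tensor(deltas), m, anchors, truths).data)
    assert lc >= 0 and np.isfinite(lc)
    assert lb >= 0 and np.isfinite(lb)
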