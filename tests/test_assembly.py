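"""Box decoding, Fast NMS and mask-assembly tests, with independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grainseg.assembly import (
    assemble_masks,
    box_iou,
    decode_boxes,
    detect,
    encode_boxes,
    fast_nms,
    finalize,
)

RNG = np.random.default_rng(31)


# ---------------------------------------------------------------------------
# box coding
# ---------------------------------------------------------------------------

def test_zero_deltas_decode_to_anchor():
    anchors = np.array([[50.0, 60.0, 20.0, 10.0]], np.float32)
    out = decode_boxes(np.zeros((1, 4), np.float32), anchors)
    assert np.allclose(out, [[40, 55, 60, 65]])


def test_delta_ln2_doubles_width():
    anchors = np.array([[50.0, 50.0, 20.0, 10.0]], np.float32)
    d = np.array([[0.0, 0.0, math.log(2) / 0.2, 0.0]], np.float32)
    out = decode_boxes(d, anchors)
    assert np.isclose(out[0, 2] - out[0, 0], 40.0, atol=1e-4)


def test_encode_decode_roundtrip():
    anchors = np.column_stack([
        RNG.uniform(20, 100, 50), RNG.uniform(20, 100, 50),
        RNG.uniform(5, 30, 50), RNG.uniform(5, 30, 50),
    ]).astype(np.float32)
    deltas = RNG.standard_normal((50, 4)).astype(np.float32)
    boxes = decode_boxes(deltas, anchors)
    assert np.allclose(encode_boxes(boxes, anchors), deltas, atol=1e-3)


def test_decode_length_mismatch():
    with pytest.raises(ValueError):
        decode_boxes(np.zeros((2, 4)), np.zeros((3, 4)))


# ---------------------------------------------------------------------------
# Fast NMS vs oracles
# ---------------------------------------------------------------------------

def naive_fast_nms(iou, thr):
    """Literal double-loop evaluation of the column-maximum rule."""
    n = iou.shape[0]
    kept = []
    for j in range(n):
        col_max = 0.0
        for i in range(n):
            if i < j:  # upper triangle only (diagonal and lower zeroed)
                col_max = max(col_max, iou[i, j])
        if col_max <= thr:
            kept.append(j)
    return np.array(kept, dtype=int)


def sequential_nms(iou, thr):
    """Classic greedy suppress-and-rescan."""
    n = iou.shape[0]
    alive = np.ones(n, bool)
    kept = []
    for i in range(n):
        if not alive[i]:
            continue
        kept.append(i)
        for j in range(i + 1, n):
            if alive[j] and iou[i, j] > thr:
                alive[j] = False
    return np.array(kept, dtype=int)


def test_single_candidate_kept():
    assert fast_nms(np.ones((1, 1, 1)), np.array([[0.9]]))[0].tolist() == [0]


def test_duplicate_boxes_keep_higher_scored():
    iou = np.ones((1, 2, 2))
    kept = fast_nms(iou, np.array([[0.9, 0.8]]), iou_thr=0.5)[0]
    assert kept.tolist() == [0]


def test_three_candidate_hand_case_subset_of_sequential():
    """IoU(1,2)=.6, IoU(1,3)=.1, IoU(2,3)=.6, thr .5: Fast NMS keeps only the
    first; sequential keeps first and third."""
    iou = np.array([[0.0, 0.6, 0.1], [0.6, 0.0, 0.6], [0.1, 0.6, 0.0]])
    np.fill_diagonal(iou, 1.0)
    kept = fast_nms(iou[None], np.array([[0.9, 0.8, 0.7]]), iou_thr=0.5)[0]
    assert kept.tolist() == [0]
    assert sequential_nms(iou, 0.5).tolist() == [0, 2]


def test_unsorted_scores_rejected():
    with pytest.raises(ValueError):
        fast_nms(np.zeros((1, 2, 2)), np.array([[0.5, 0.9]]))


def test_fast_nms_random_instances_match_double_loop_and_subset():
    """200 random instances: exact index agreement with the double-loop
    oracle, and kept(fast) is a subset of kept(sequential)."""
    rng = np.random.default_rng(99)
    for _ in range(200):
        n = int(rng.integers(1, 51))
        boxes = np.column_stack([
            rng.uniform(0, 80, n), rng.uniform(0, 80, n),
            rng.uniform(5, 40, n), rng.uniform(5, 40, n),
        ])
        boxes[:, 2:] += boxes[:, :2]
        scores = np.sort(rng.random(n))[::-1]
        iou = box_iou(boxes, boxes)
        thr = float(rng.uniform(0.2, 0.7))
        kept = fast_nms(iou[None], scores[None], thr)[0]
        assert np.array_equal(kept, naive_fast_nms(iou, thr))
        assert set(kept.tolist()) <= set(sequential_nms(iou, thr).tolist())


def test_detect_caps_instance_count():
    n, c = 50, 4
    boxes = np.column_stack([
        RNG.uniform(0, 100, n), RNG.uniform(0, 100, n),
        np.full(n, 10.0), np.full(n, 10.0),
    ]).astype(np.float32)
    boxes[:, 2:] += boxes[:, :2]
    scores = RNG.random((n, c + 1)).astype(np.float32)
    coefs = RNG.standard_normal((n, 8)).astype(np.float32)
    out = detect(boxes, scores, coefs, top_n=20, max_dets=10)
    assert len(out["scores"]) <= 10
    assert len(out["scores"]) <= 20 * c


# ---------------------------------------------------------------------------
# mask assembly
# ---------------------------------------------------------------------------

def test_zero_coefficients_give_half_mask():
    P = RNG.standard_normal((4, 4, 3)).astype(np.float32)
    M = assemble_masks(P, np.zeros((1, 3), np.float32))
    assert np.allclose(M, 0.5)


def test_one_hot_saturation():
    P = np.zeros((4, 4, 2), np.float32)
    P[:2, :, 0] = 3.0  # prototype 0 active in the top half
    C = np.array([[50.0, 0.0]], np.float32)
    M = assemble_masks(P, C)
    assert np.allclose(M[:2, :, 0], 1.0, atol=1e-4)
    assert np.allclose(M[2:, :, 0], 0.5)


def test_two_prototype_difference_hand_case():
    P = np.stack([
        np.array([[1.0, -2.0], [0.5, 3.0]], np.float32),
        np.array([[2.0, 1.0], [-1.0, 3.0]], np.float32),
    ], axis=-1)
    M = assemble_masks(P, np.array([[1.0, -1.0]], np.float32))
    expect = 1 / (1 + np.exp(-(P[:, :, 0] - P[:, :, 1])))
    assert np.allclose(M[:, :, 0], expect, atol=1e-6)


def test_prototype_count_mismatch():
    with pytest.raises(ValueError):
        assemble_masks(np.zeros((2, 2, 3)), np.zeros((1, 4)))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 3), st.floats(0.1, 2.0))
def test_assembly_monotone_in_coefficients(j, delta):
    """Raising C[0, j] never lowers the mask where prototype j is positive."""
    rng = np.random.default_rng(7)
    P = np.abs(rng.standard_normal((5, 5, 4))).astype(np.float32)
    C = rng.standard_normal((1, 4)).astype(np.float32)
    C2 = C.copy()
    C2[0, j] += delta
    M1, M2 = assemble_masks(P, C), assemble_masks(P, C2)
    assert np.all(M2[:, :, 0][P[:, :, j] > 0] >= M1[:, :, 0][P[:, :, j] > 0])


# ---------------------------------------------------------------------------
# finalisation
# ---------------------------------------------------------------------------

def test_finalize_zero_threshold_keeps_all_inbox_pixels():
    masks = np.full((8, 8, 1), 0.2, np.float32)
    out = finalize(masks, np.array([[2.0, 2.0, 6.0, 6.0]]),
                   np.array([0.9]), np.array([0]), (8, 8),
                   score_thr=0.0, mask_thr=0.0, box_expand=0.0)
    assert out["masks"][0].sum() == 16  # the 4x4 box interior


def test_finalize_mask_outside_box_is_empty():
    masks = np.zeros((8, 8, 1), np.float32)
    masks[:2, :2, 0] = 0.99
    out = finalize(masks, np.array([[5.0, 5.0, 8.0, 8.0]]),
                   np.array([0.9]), np.array([0]), (8, 8),
                   score_thr=0.0, mask_thr=0.5, box_expand=0.0)
    assert out["masks"][0].sum() == 0


def test_finalize_uniform_mask_crops_to_exact_box():
    masks = np.full((8, 8, 1), 0.6, np.float32)
    out = finalize(masks, np.array([[2.0, 3.0, 5.0, 6.0]]),
                   np.array([0.9]), np.array([0]), (8, 8),
                   score_thr=0.0, mask_thr=0.5, box_expand=0.0)
    assert out["masks"][0].sum() == 9
    assert out["masks"][0][3:6, 2:5].all()


def test_finalize_drops_low_scores():
    masks = np.full((4, 4, 2), 0.9, np.float32)
    out = finalize(masks, np.array([[0, 0, 4, 4], [0, 0, 4, 4]], float),
                   np.array([0.9, 0.01]), np.array([0, 1]), (4, 4),
                   score_thr=0.05)
    assert len(out["scores"]) == 1 and out["classes"][0] == 0
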