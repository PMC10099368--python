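"""Evaluation stack: closed-form precision/recall/mAP values, NMS and AP
against brute-force oracles, matching fixtures and report invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uwdet.metrics import (Detection, MatchTally, ap_from_ranked,
                           average_precision, confusion_matrix, evaluate, iou,
                           iou_matrix, match_detections, mean_ap, nms,
                           precision, recall, IOU_THRESHOLDS)


# -- IoU ---------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ((0, 0, 2, 2), (0, 0, 2, 2), 1.0),
    ((0, 0, 2, 2), (1, 1, 3, 3), 1 / 7),
    ((0, 0, 1, 1), (2, 2, 3, 3), 0.0),
])
def test_iou_closed_forms(a, b, expected):
    assert iou(a, b) == pytest.approx(expected)


def test_iou_matrix_bounds(rng):
    a = np.sort(rng.random((20, 4)) * 10, axis=-1)[:, [0, 1, 2, 3]]
    a = np.column_stack([a[:, 0], a[:, 1], a[:, 0] + a[:, 2] + 0.1,
                         a[:, 1] + a[:, 3] + 0.1])
    m = iou_matrix(a, a)
    assert (m >= 0).all() and (m <= 1 + 1e-12).all()
    np.testing.assert_allclose(np.diag(m), 1.0)


# -- NMS ---------------------------------------------------------------------

def nms_oracle(dets, iou_thresh, conf_thresh):
    """Quadratic greedy suppression written independently with plain loops."""
    pool = [d for d in dets if d[4] >= conf_thresh]
    pool.sort(key=lambda d: -d[4])
    kept = []
    for d in pool:
        ok = True
        for k in kept:
            if k[5] == d[5] and iou(k[:4], d[:4]) > iou_thresh:
                ok = False
                break
        if ok:
            kept.append(d)
    return np.array(kept).reshape(-1, 6)


def test_nms_suppresses_duplicates():
    dets = np.array([[0, 0, 10, 10, 0.9, 0], [0, 0, 10, 10, 0.8, 0]])
    out = nms(dets, 0.5, 0.1)
    assert len(out) == 1 and out[0, 4] == 0.9


def test_nms_keeps_disjoint_and_cross_class():
    dets = np.array([[0, 0, 10, 10, 0.9, 0], [20, 20, 30, 30, 0.5, 0],
                     [0, 0, 10, 10, 0.8, 1]])
    assert len(nms(dets, 0.5, 0.1)) == 3


def test_nms_agrees_with_quadratic_oracle(rng):
    xy = rng.random((50, 2)) * 80
    wh = rng.random((50, 2)) * 30 + 2
    dets = np.column_stack([xy, xy + wh, rng.random(50),
                            rng.integers(0, 3, 50).astype(float)])
    ours = nms(dets, 0.5, 0.2)
    oracle = nms_oracle(list(dets), 0.5, 0.2)
    np.testing.assert_allclose(np.sort(ours, axis=0),
                               np.sort(oracle, axis=0))


# -- matching ----------------------------------------------------------------

def test_match_perfect_predictions():
    truths = np.array([[0, 0, 10, 10, 0], [20, 20, 30, 30, 1]])
    dets = np.column_stack([truths[:, :4], [0.9, 0.8], truths[:, 4]])
    tallies = match_detections(dets, truths, 0.5)
    for cls in (0, 1):
        assert (tallies[cls].tp, tallies[cls].fp, tallies[cls].fn) == (1, 0, 0)


def test_match_detection_without_truth_is_fp():
    tallies = match_detections(np.array([[0, 0, 5, 5, 0.9, 2]]),
                               np.zeros((0, 5)), 0.5)
    assert (tallies[2].tp, tallies[2].fp, tallies[2].fn) == (0, 1, 0)


def test_match_crafted_five_det_three_truth_fixture():
    """Hand enumeration at IoU 0.5: d0 takes t0, d1 overlaps t0 only (FP),
    d2 takes t1, d3 misses everything (FP), d4 takes t2."""
    truths = np.array([[0, 0, 10, 10, 0], [20, 0, 30, 10, 0],
                       [40, 0, 50, 10, 0]])
    dets = np.array([
        [0, 0, 10, 10, 0.95, 0],     # exact on t0
        [1, 1, 11, 11, 0.90, 0],     # best left is t0 (used) -> FP
        [20, 1, 30, 11, 0.85, 0],    # IoU 0.8 with t1
        [70, 70, 80, 80, 0.80, 0],   # far away -> FP
        [41, 0, 50, 10, 0.75, 0],    # IoU 0.9 with t2
    ])
    t = match_detections(dets, truths, 0.5)[0]
    assert (t.tp, t.fp, t.fn) == (3, 2, 0)
    assert t.tp + t.fn == len(truths)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.data())
def test_match_conservation_property(data):
    n_t = data.draw(st.integers(0, 6))
    n_d = data.draw(st.integers(0, 6))
    seed = data.draw(st.integers(0, 10_000))
    rng = np.random.default_rng(seed)
    truths = np.column_stack([
        rng.random((n_t, 2)) * 50,
        rng.random((n_t, 2)) * 50 + 55,
        rng.integers(0, 2, n_t)]) if n_t else np.zeros((0, 5))
    dets = np.column_stack([
        rng.random((n_d, 2)) * 50,
        rng.random((n_d, 2)) * 50 + 55,
        rng.random(n_d),
        rng.integers(0, 2, n_d)]) if n_d else np.zeros((0, 6))
    tallies = match_detections(dets, truths, 0.5, num_classes=2)
    for cls, t in tallies.items():
        assert t.tp + t.fn == (truths[:, 4] == cls).sum()
        assert t.tp + t.fp == (dets[:, 5] == cls).sum()
        assert min(t.tp, t.fp, t.fn) >= 0


# -- precision / recall ------------------------------------------------------

@pytest.mark.parametrize("tp,fp,expected", [(10, 0, 1.0), (0, 5, 0.0),
                                            (3, 1, 0.75), (0, 0, 0.0)])
def test_precision_closed_form(tp, fp, expected):
    assert precision(MatchTally(tp=tp, fp=fp)) == pytest.approx(expected)


@pytest.mark.parametrize("tp,fn,expected", [(10, 0, 1.0), (0, 4, 0.0),
                                            (2, 2, 0.5), (0, 0, 0.0)])
def test_recall_closed_form(tp, fn, expected):
    assert recall(MatchTally(tp=tp, fn=fn)) == pytest.approx(expected)


# -- AP ----------------------------------------------------------------------

def ap_dense_threshold_oracle(flags, n_truths, n_recall=20001):
    """Independent AP: evaluate (recall, envelope precision) by brute-force
    threshold sweep, then integrate the envelope on a fine recall grid."""
    confs = np.linspace(1, 0, len(flags), endpoint=False)  # ranked scores
    points = []
    for thr in np.unique(np.concatenate([confs, [0, 1.001]])):
        sel = confs >= thr
        tp = flags[sel].sum()
        fp = sel.sum() - tp
        r = tp / n_truths if n_truths else 0.0
        p = tp / (tp + fp) if (tp + fp) else 1.0
        points.append((r, p))
    grid = np.linspace(0, 1, n_recall)
    env = np.zeros_like(grid)
    for r, p in points:
        env[grid <= r] = np.maximum(env[grid <= r], p)
    return env.mean()


def test_ap_perfect_and_zero():
    assert ap_from_ranked(np.array([True, True, True]), 3) == pytest.approx(1.0)
    assert ap_from_ranked(np.array([False, False]), 3) == 0.0
    assert ap_from_ranked(np.array([]), 0) == 0.0


def test_ap_six_detection_fixture_matches_dense_integration_oracle():
    flags = np.array([True, False, True, True, False, True])
    expected = ap_dense_threshold_oracle(flags, n_truths=5)
    got = ap_from_ranked(flags, 5, mode="continuous")
    assert got == pytest.approx(expected, abs=1e-3)
    # the 101-point COCO variant agrees closely but not exactly
    assert abs(ap_from_ranked(flags, 5) - expected) < 0.02


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.booleans(), min_size=1, max_size=10),
       st.integers(1, 12))
def test_ap_continuous_always_matches_oracle(flags, extra_fn):
    flags = np.array(flags)
    n_truths = int(flags.sum()) + extra_fn
    expected = ap_dense_threshold_oracle(flags, n_truths)
    assert ap_from_ranked(flags, n_truths, mode="continuous") == \
        pytest.approx(expected, abs=1e-3)


def test_ap_invariant_to_monotone_confidence_rescale(rng):
    truths = np.column_stack([rng.random((5, 2)) * 40,
                              rng.random((5, 2)) * 40 + 45])
    dets = np.column_stack([truths + rng.normal(0, 3, truths.shape),
                            rng.random(5)])
    base = average_precision(dets, truths, 0.5)
    squashed = dets.copy()
    squashed[:, 4] = 1 / (1 + np.exp(-5 * squashed[:, 4]))  # monotone map
    assert average_precision(squashed, truths, 0.5) == pytest.approx(base)


# -- mAP ---------------------------------------------------------------------

def test_mean_ap_closed_forms():
    assert mean_ap({0: 1.0, 1: 1.0}) == 1.0
    assert mean_ap([1.0, 0.5]) == pytest.approx(0.75)


def test_threshold_grid_has_ten_entries():
    assert len(IOU_THRESHOLDS) == 10
    np.testing.assert_allclose(IOU_THRESHOLDS,
                               [0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85,
                                0.9, 0.95])


def test_map_50_95_not_above_map50(rng):
    truths, dets = [], []
    for _ in range(4):
        t = np.column_stack([rng.random((3, 2)) * 40,
                             rng.random((3, 2)) * 40 + 45,
                             rng.integers(0, 2, 3)])
        jitter = rng.normal(0, 2.5, (3, 4))
        d = np.column_stack([t[:, :4] + jitter, rng.random(3), t[:, 4]])
        truths.append(t)
        dets.append(d)
    report = evaluate(dets, truths, num_classes=2)
    assert report.map50_95 <= report.map50 + 1e-12
    assert 0.0 <= report.map50 <= 1.0


# -- confusion matrix --------------------------------------------------------

def test_confusion_all_correct_is_diagonal():
    truths = [np.array([[0, 0, 10, 10, 0], [20, 20, 30, 30, 1]])]
    dets = [np.column_stack([truths[0][:, :4], [0.9, 0.9], truths[0][:, 4]])]
    m = confusion_matrix(dets, truths, num_classes=2)
    assert m[0, 0] == 1 and m[1, 1] == 1
    assert m.sum() == 2


def test_confusion_wrong_class_single_off_diagonal():
    truths = [np.array([[0, 0, 10, 10, 0]])]
    dets = [np.array([[0, 0, 10, 10, 0.9, 1]])]
    m = confusion_matrix(dets, truths, num_classes=2)
    assert m[0, 1] == 1 and m.sum() == 1


def test_confusion_three_image_fixture_hand_enumeration():
    truths = [
        np.array([[0, 0, 10, 10, 0]]),                  # detected correctly
        np.array([[0, 0, 10, 10, 1]]),                  # missed
        np.array([[0, 0, 10, 10, 2], [30, 30, 40, 40, 0]]),
    ]
    dets = [
        np.array([[0, 0, 10, 10, 0.9, 0]]),
        np.zeros((0, 6)),
        np.array([[0, 0, 10, 10, 0.8, 2],               # correct
                  [60, 60, 70, 70, 0.7, 1]]),           # spurious
    ]
    m = confusion_matrix(dets, truths, num_classes=3)
    expected = np.zeros((4, 4), dtype=int)
    expected[0, 0] = 1          # image 0
    expected[1, 3] = 1          # image 1: truth 1 missed -> background col
    expected[2, 2] = 1          # image 2 correct
    expected[0, 3] = 1          # image 2: truth 0 missed
    expected[3, 1] = 1          # image 2: spurious class-1 detection
    np.testing.assert_array_equal(m, expected)


def test_detection_type_validation():
    with pytest.raises(ValueError):
        Detection(box=(5, 5, 1, 8), confidence=0.5, class_id=0)
    with pytest.raises(ValueError):
        Detection(box=(0, 0, 1, 1), confidence=float("nan"), class_id=0)
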