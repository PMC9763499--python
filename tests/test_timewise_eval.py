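"""Time-wise PREC/TPR, merging, frame ROC/AUC, confusion matrix and UAR.

Brute-force oracles work on a 1 ms grid: intervals are generated on grid
multiples, so boolean masks over the grid give exact durations that the
interval arithmetic must reproduce.
"""

import numpy as np
import pytest

from callfinder.segmentation import Annotation, FrameScore
from callfinder.timewise_eval import (
    TimewiseEvalConfig,
    confusion_and_uar,
    frame_roc_auc,
    merge_ground_truth,
    timewise_precision_recall,
)

GRID = 1e-3  # seconds


def _random_intervals(rng, horizon=20.0, max_n=6):
    out = []
    for _ in range(int(rng.integers(0, max_n + 1))):
        start = int(rng.integers(0, int(horizon / GRID) - 200))
        length = int(rng.integers(50, 2000))
        out.append(Annotation(start * GRID, min((start + length) * GRID, horizon), "target"))
    return sorted(out, key=lambda a: a.start)


def _mask(intervals, horizon=20.0):
    grid = np.zeros(int(round(horizon / GRID)), dtype=bool)
    for a in intervals:
        grid[int(round(a.start / GRID)) : int(round(a.end / GRID))] = True
    return grid


# ------------------------------------------------------------------- merging

def test_merge_examples():
    cfg = TimewiseEvalConfig(merge_xi=0.5, extend_lambda=0.0)
    merged = merge_ground_truth(
        [Annotation(0, 1, "t"), Annotation(1.2, 2, "t")], cfg
    )
    assert [(a.start, a.end) for a in merged] == [(0, 2)]

    merged = merge_ground_truth([Annotation(0, 1, "t"), Annotation(2, 3, "t")], cfg)
    assert [(a.start, a.end) for a in merged] == [(0, 1), (2, 3)]

    merged = merge_ground_truth(
        [Annotation(0, 1, "t"), Annotation(1.3, 2, "t"), Annotation(2.2, 3, "t")], cfg
    )
    assert [(a.start, a.end) for a in merged] == [(0, 3)]


def test_merging_is_idempotent_and_order_independent(rng):
    cfg = TimewiseEvalConfig(merge_xi=0.3, extend_lambda=0.0)
    for _ in range(50):
        gt = _random_intervals(rng)
        once = merge_ground_truth(gt, cfg)
        twice = merge_ground_truth(once, cfg)
        assert once == twice
        shuffled = [gt[i] for i in rng.permutation(len(gt))]
        assert merge_ground_truth(shuffled, cfg) == once


def test_xi_merging_matches_grid_oracle(rng):
    for _ in range(200):
        xi_ms = int(rng.integers(0, 600))
        cfg = TimewiseEvalConfig(merge_xi=xi_ms * GRID, extend_lambda=0.0)
        gt = _random_intervals(rng)
        merged = merge_ground_truth(gt, cfg)
        # oracle: dilate by xi/2 on the grid, take connected components, undo
        if not gt:
            assert merged == []
            continue
        starts = [int(round(a.start / GRID)) for a in gt]
        ends = [int(round(a.end / GRID)) for a in gt]
        events = sorted(zip(starts, ends))
        expected = [list(events[0])]
        for s, e in events[1:]:
            if s - expected[-1][1] <= xi_ms:
                expected[-1][1] = max(expected[-1][1], e)
            else:
                expected.append([s, e])
        got = [(int(round(a.start / GRID)), int(round(a.end / GRID))) for a in merged]
        assert got == [tuple(x) for x in expected]


# ----------------------------------------------------- time-wise PREC / TPR

def test_worked_interval_example_exact():
    cfg = TimewiseEvalConfig(merge_xi=0.5, extend_lambda=0.25)
    prec, tpr = timewise_precision_recall(
        [Annotation(0.8, 1.9, "target")], [Annotation(1.0, 2.0, "target")], cfg
    )
    assert prec == 1.0
    assert abs(tpr - 0.9) < 1e-12


def test_perfect_prediction_gives_unit_scores(rng):
    cfg = TimewiseEvalConfig(merge_xi=0.5, extend_lambda=0.25)
    gt = _random_intervals(rng, max_n=4) or [Annotation(1, 2, "target")]
    merged = merge_ground_truth(gt, cfg)
    prec, tpr = timewise_precision_recall(merged, gt, cfg)
    assert prec == 1.0 and abs(tpr - 1.0) < 1e-12


def test_disjoint_prediction_gives_zero_precision():
    cfg = TimewiseEvalConfig(merge_xi=0.1, extend_lambda=0.1)
    prec, tpr = timewise_precision_recall(
        [Annotation(10.0, 11.0, "target")], [Annotation(0.0, 1.0, "target")], cfg
    )
    assert prec == 0.0 and tpr == 0.0


def test_empty_cases_reported_as_not_available():
    cfg = TimewiseEvalConfig(merge_xi=0.1, extend_lambda=0.1)
    prec, tpr = timewise_precision_recall([], [Annotation(0, 1, "t")], cfg)
    assert prec is None and tpr == 0.0
    prec, tpr = timewise_precision_recall([Annotation(0, 1, "t")], [], cfg)
    assert prec == 0.0 and tpr is None


def test_timewise_scores_match_grid_oracle(rng):
    horizon = 20.0
    for _ in range(200):
        pred = _random_intervals(rng)
        gt = _random_intervals(rng)
        if not pred or not gt:
            continue
        xi = int(rng.integers(0, 500)) * GRID
        lam = int(rng.integers(0, 500)) * GRID
        cfg = TimewiseEvalConfig(merge_xi=xi, extend_lambda=lam)
        prec, tpr = timewise_precision_recall(pred, gt, cfg, recording_bounds=(0, horizon))

        merged = merge_ground_truth(gt, cfg)
        extended = [
            Annotation(max(a.start - lam, 0.0), min(a.end + lam, horizon), "t")
            for a in merged
        ]
        pred_mask = _mask(pred, horizon)
        gt_mask = _mask(merged, horizon)
        ext_mask = _mask(extended, horizon)
        prec_oracle = (pred_mask & ext_mask).sum() / pred_mask.sum()
        tpr_oracle = (pred_mask & gt_mask).sum() / gt_mask.sum()
        assert abs(prec - prec_oracle) < 1e-9
        assert abs(tpr - tpr_oracle) < 1e-9


def test_scores_invariant_to_splitting_predictions(rng):
    cfg = TimewiseEvalConfig(merge_xi=0.2, extend_lambda=0.3)
    gt = [Annotation(2.0, 4.0, "t"), Annotation(6.0, 7.0, "t")]
    pred = [Annotation(1.5, 4.5, "t"), Annotation(6.2, 6.8, "t")]
    split_pred = [
        Annotation(1.5, 2.5, "t"), Annotation(2.5, 3.1, "t"), Annotation(3.1, 4.5, "t"),
        Annotation(6.2, 6.5, "t"), Annotation(6.5, 6.8, "t"),
    ]
    assert timewise_precision_recall(pred, gt, cfg) == pytest.approx(
        timewise_precision_recall(split_pred, gt, cfg)
    )


# ------------------------------------------------------------ frame ROC/AUC

def _scored_frames(scores, eps=1.0, kappa=1.0):
    return [
        FrameScore(i * kappa, i * kappa + eps, {"target": float(s), "noise": 1 - float(s)},
                   "target" if s > 0.5 else "noise")
        for i, s in enumerate(scores)
    ]


def test_perfectly_separating_scores_give_auc_one():
    frames = _scored_frames([0.9, 0.8, 0.2, 0.1])
    gt = [Annotation(0.0, 2.0, "target")]  # first two frames positive
    _, auc = frame_roc_auc(frames, gt)
    assert auc == 1.0


def test_constant_scores_give_auc_half():
    frames = _scored_frames([0.5, 0.5, 0.5, 0.5])
    gt = [Annotation(0.0, 2.0, "target")]
    _, auc = frame_roc_auc(frames, gt)
    assert abs(auc - 0.5) < 1e-12


def test_pair_counting_example():
    frames = _scored_frames([0.9, 0.8, 0.7, 0.1])
    gt = [Annotation(0.0, 2.0, "target")]
    _, auc = frame_roc_auc(frames, gt)
    assert auc == 1.0


def test_single_class_ground_truth_has_no_auc():
    frames = _scored_frames([0.9, 0.8])
    _, auc = frame_roc_auc(frames, [Annotation(0.0, 2.0, "target")])
    assert auc is None


def test_auc_matches_mann_whitney_oracle(rng):
    # oracle: count concordant pairs, half credit for ties
    for _ in range(200):
        n = int(rng.integers(3, 30))
        scores = np.round(rng.random(n), 2)  # coarse grid provokes ties
        labels = rng.random(n) > 0.5
        if labels.all() or (~labels).any() is False or not labels.any():
            continue
        frames = _scored_frames(scores)
        gt = [
            Annotation(i * 1.0, i * 1.0 + 1.0, "target")
            for i in range(n)
            if labels[i]
        ]
        _, auc = frame_roc_auc(frames, gt)
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert abs(auc - wins / (len(pos) * len(neg))) < 1e-9


def test_auc_agrees_with_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    scores = rng.random(50)
    labels = rng.random(50) > 0.4
    labels[0], labels[1] = True, False
    frames = _scored_frames(scores)
    gt = [Annotation(i, i + 1.0, "t") for i in range(50) if labels[i]]
    _, auc = frame_roc_auc(frames, gt)
    assert abs(auc - roc_auc_score(labels, scores)) < 1e-9


def test_frame_labels_use_majority_overlap():
    frames = [
        FrameScore(0.0, 1.0, {"target": 0.9, "noise": 0.1}, "target"),
        FrameScore(1.0, 2.0, {"target": 0.9, "noise": 0.1}, "target"),
    ]
    gt = [Annotation(0.0, 1.4, "target")]  # 100% of frame 1, 40% of frame 2
    from callfinder.timewise_eval import frame_ground_truth

    labels = frame_ground_truth(frames, gt)
    assert labels.tolist() == [True, False]


# ------------------------------------------------------- confusion and UAR

def test_perfect_predictions_give_uar_one():
    pairs = [("a", "a")] * 5 + [("b", "b")] * 2
    matrix, uar = confusion_and_uar(pairs, ["a", "b"])
    assert uar == 1.0
    assert matrix.tolist() == [[5, 0], [0, 2]]


def test_worked_two_class_uar():
    pairs = [("a", "a")] * 8 + [("a", "b")] * 2 + [("b", "a")] * 5 + [("b", "b")] * 5
    matrix, uar = confusion_and_uar(pairs, ["a", "b"])
    assert matrix.tolist() == [[8, 2], [5, 5]]
    assert abs(uar - 0.65) < 1e-12


def test_zero_recall_class_included_in_uar():
    pairs = (
        [("a", "a")] * 4 + [("b", "b")] * 4 + [("c", "c")] * 4 + [("d", "a")] * 4
    )
    _, uar = confusion_and_uar(pairs, ["a", "b", "c", "d"])
    assert abs(uar - 0.75) < 1e-12  # (1 + 1 + 1 + 0) / 4


def test_unsupported_class_excluded_with_warning():
    pairs = [("a", "a"), ("b", "a")]
    with pytest.warns(UserWarning):
        _, uar = confusion_and_uar(pairs, ["a", "b", "ghost"])
    assert abs(uar - 0.5) < 1e-12


def test_uar_invariant_to_class_size_rescaling(rng):
    pairs = [("a", rng.choice(["a", "b"])) for _ in range(20)]
    pairs += [("b", rng.choice(["a", "b"])) for _ in range(10)]
    _, uar = confusion_and_uar(pairs, ["a", "b"])
    duplicated = pairs + [p for p in pairs if p[0] == "b"]
    _, uar2 = confusion_and_uar(duplicated, ["a", "b"])
    assert abs(uar - uar2) < 1e-12


def test_empty_pairs_rejected():
    with pytest.raises(ValueError):
        confusion_and_uar([], ["a"])
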