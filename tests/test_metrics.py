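"""Overlap metrics, confusion counts and the Tversky index/loss."""

from fractions import Fraction

import numpy as np
import pytest

from xletseg.metrics import (
    ConfusionCounts,
    TverskyParams,
    aggregate_report,
    confusion_counts,
    dice,
    image_row,
    jaccard,
    sensitivity_fpr,
    soft_tversky_index,
    tversky_index,
    tversky_loss,
)


def _worked_case():
    """4x4 masks: |truth| = 4, |pred| = 6, overlap 3."""
    truth = np.zeros((4, 4), dtype=int)
    truth[0, 0:4] = 1
    pred = np.zeros((4, 4), dtype=int)
    pred[0, 0:3] = 1  # 3 overlapping
    pred[1, 0:3] = 1  # 3 false positives
    return pred, truth


def test_confusion_counts_worked_case():
    pred, truth = _worked_case()
    c = confusion_counts(pred, truth)
    assert (c.TP, c.FP, c.FN, c.TN) == (3, 3, 1, 9)
    assert c.P == 4 and c.N == 12 and c.total == 16


def test_confusion_counts_degenerate_cases(rng):
    truth = (rng.random((8, 8)) > 0.6).astype(int)
    k = int(truth.sum())
    c = confusion_counts(truth, truth)
    assert (c.TP, c.FP, c.FN, c.TN) == (k, 0, 0, 64 - k)
    c = confusion_counts(1 - truth, truth)
    assert c.TP == 0 and c.TN == 0


def test_dice_and_jaccard_values():
    pred, truth = _worked_case()
    assert dice(pred, truth) == pytest.approx(0.6)
    assert jaccard(pred, truth) == pytest.approx(3 / 7)
    ones = np.ones((4, 4), dtype=int)
    zeros = np.zeros((4, 4), dtype=int)
    assert dice(ones, ones) == 1.0 and jaccard(ones, ones) == 1.0
    assert dice(zeros, ones) == 0.0
    assert dice(zeros, zeros) == 1.0 and jaccard(zeros, zeros) == 1.0  # convention


def test_jaccard_dice_identity_exact(rng):
    """J = D/(2-D) as exact rationals on random mask pairs; 0<=J<=D<=1."""
    for _ in range(100):
        pred = (rng.random((8, 8)) > 0.5).astype(int)
        truth = (rng.random((8, 8)) > 0.5).astype(int)
        c = confusion_counts(pred, truth)
        d_frac = Fraction(2 * c.TP, 2 * c.TP + c.FP + c.FN) if 2 * c.TP + c.FP + c.FN else Fraction(1)
        j_frac = Fraction(c.TP, c.TP + c.FP + c.FN) if c.TP + c.FP + c.FN else Fraction(1)
        assert j_frac == d_frac / (2 - d_frac)
        d, j = dice(pred, truth), jaccard(pred, truth)
        assert 0.0 <= j <= d <= 1.0
        assert j == pytest.approx(d / (2.0 - d), rel=1e-12)


def test_sensitivity_fpr():
    pred, truth = _worked_case()
    sen, fpr = sensitivity_fpr(confusion_counts(pred, truth))
    assert sen == pytest.approx(75.0) and fpr == pytest.approx(25.0)
    sen, fpr = sensitivity_fpr(confusion_counts(truth, truth))
    assert sen == 100.0 and fpr == 0.0
    sen, fpr = sensitivity_fpr(confusion_counts(np.ones_like(truth), truth))
    assert sen == 100.0 and fpr == 100.0
    with pytest.raises(ZeroDivisionError):
        sensitivity_fpr(confusion_counts(np.zeros((4, 4)), np.zeros((4, 4))))
    with pytest.raises(ZeroDivisionError):
        sensitivity_fpr(confusion_counts(np.ones((4, 4)), np.ones((4, 4))))


def test_tversky_index_values_and_identities(rng):
    pred, truth = _worked_case()
    c = confusion_counts(pred, truth)
    assert tversky_index(c, TverskyParams(0.8, 0.2)) == pytest.approx(3 / 4.4)
    assert tversky_index(confusion_counts(truth, truth), TverskyParams()) == 1.0
    # alpha = beta = 1/2 reduces to Dice, exactly
    half = TverskyParams(0.5, 0.5)
    for _ in range(20):
        p = (rng.random((8, 8)) > 0.5).astype(int)
        t = (rng.random((8, 8)) > 0.5).astype(int)
        assert tversky_index(confusion_counts(p, t), half) == dice(p, t)


def test_tversky_monotonicity():
    params = TverskyParams(0.8, 0.2)
    base = tversky_index(ConfusionCounts(10, 5, 5, 80), params)
    assert tversky_index(ConfusionCounts(10, 6, 5, 79), params) < base  # more FP
    assert tversky_index(ConfusionCounts(10, 5, 6, 79), params) < base  # more FN
    assert tversky_index(ConfusionCounts(11, 5, 5, 79), params) > base  # more TP


def test_soft_tversky_loss_cases(rng):
    t = (rng.random((16, 16)) > 0.7).astype(int)
    params = TverskyParams(0.8, 0.2, epsilon=1e-6)
    assert tversky_loss(t.astype(float), t, params) <= 1e-4
    assert tversky_loss(1.0 - t.astype(float), t, params) >= 1.0 - 1e-4
    # hard probabilities reproduce the integer-count index exactly
    p = (rng.random((16, 16)) > 0.5).astype(float)
    exact = TverskyParams(0.8, 0.2, epsilon=0.0)
    soft = soft_tversky_index(p, t, exact)
    hard = tversky_index(confusion_counts(p.astype(int), t), exact)
    assert soft == hard


def test_tversky_params_validation():
    with pytest.raises(ValueError):
        TverskyParams(0.0, 0.0)
    with pytest.raises(ValueError):
        TverskyParams(-0.1, 0.5)


def test_aggregate_report(rng):
    truth = (rng.random((8, 8)) > 0.6).astype(int)
    rows = [image_row(f"im{i}", truth, truth) for i in range(1)]
    rep = aggregate_report(rows)
    assert rep.summary.loc[0, "dice"] == rep.summary.loc[1, "dice"] == 1.0

    vals = [0.2, 0.9, 0.4, 0.8, 0.6]
    rows = [
        {"image_id": f"im{i}", "dice": v, "jaccard": v, "sen_pct": 100 * v, "fpr_pct": 0.0}
        for i, v in enumerate(vals)
    ]
    rep = aggregate_report(rows)
    assert rep.summary.loc[0, "dice"] == pytest.approx(np.mean(vals))
    assert rep.summary.loc[1, "dice"] == pytest.approx(sorted(vals)[2])
    assert list(rep.per_image["image_id"]) == [f"im{i}" for i in range(5)]
    with pytest.raises(ValueError):
        aggregate_report([])


def test_metrics_invariant_to_pixel_permutation(rng):
    pred = (rng.random((8, 8)) > 0.5).astype(int)
    truth = (rng.random((8, 8)) > 0.5).astype(int)
    perm = rng.permutation(64)
    pp = pred.ravel()[perm].reshape(8, 8)
    tp = truth.ravel()[perm].reshape(8, 8)
    assert dice(pp, tp) == dice(pred, truth)
    assert jaccard(pp, tp) == jaccard(pred, truth)
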