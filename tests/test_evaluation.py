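"""Binarization, the eight-column metric report, and McNemar comparisons."""

import numpy as np
import pytest

from sonoseg import (
    LossConfig,
    binarize,
    bonferroni_threshold,
    compare_models,
    compute_metrics,
    confusion_counts,
    evaluate_predictions,
    mcnemar_pixelwise,
)
from sonoseg.evaluation import METRIC_COLUMNS, ConfusionCounts


# ------------------------------------------------------------------ binarize

def test_binarize_thresholds_with_tie_as_foreground():
    prob = np.array([0.4, 0.5, 0.6])
    np.testing.assert_array_equal(binarize(prob), [0, 1, 1])
    np.testing.assert_array_equal(binarize(np.full((3, 3), 0.4)), np.zeros((3, 3)))


def test_binarize_complement_identity_off_ties(rng):
    p = rng.random(500)
    p = p[np.abs(p - 0.5) > 1e-9]
    np.testing.assert_array_equal(binarize(p), 1 - binarize(1.0 - p))


def test_binarize_rejects_degenerate_threshold():
    for t in (0.0, 1.0, -0.2):
        with pytest.raises(ValueError):
            binarize(np.array([0.5]), threshold=t)


# ----------------------------------------------------------------- confusion

def test_confusion_counts_on_hand_marked_grid():
    truth = np.array(
        [[1, 1, 0, 0],
         [1, 1, 0, 0],
         [0, 0, 0, 0],
         [0, 0, 0, 1]]
    )
    pred = np.array(
        [[1, 0, 0, 0],
         [1, 1, 1, 0],
         [0, 0, 0, 0],
         [0, 0, 0, 0]]
    )
    c = confusion_counts(truth, pred)
    assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 2, 10)
    assert c.total == truth.size


def test_confusion_degenerate_extremes(rng):
    t = (rng.random((6, 6)) > 0.5).astype(int)
    perfect = confusion_counts(t, t)
    assert perfect.fp == perfect.fn == 0
    inverted = confusion_counts(t, 1 - t)
    assert inverted.tp == inverted.tn == 0


def test_confusion_shape_mismatch_raises():
    with pytest.raises(ValueError):
        confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))


# ------------------------------------------------------------------- metrics

def test_metric_report_hand_arithmetic():
    counts = ConfusionCounts(tp=90, fp=10, tn=880, fn=20)
    r = compute_metrics(counts, loss=0.5, dice=0.9)
    assert r.accuracy == pytest.approx(0.97)
    assert r.precision == pytest.approx(0.9)
    assert r.sensitivity == pytest.approx(0.818182, abs=1e-6)
    assert r.specificity == pytest.approx(0.988764, abs=1e-6)
    assert r.f1 == pytest.approx(0.857143, abs=1e-6)
    assert r.dice_loss == pytest.approx(1 - 0.9)


def test_metric_report_invariants(rng):
    truth = (rng.random((3, 16, 16)) > 0.7).astype(float)
    prob = np.clip(truth * 0.8 + rng.random(truth.shape) * 0.2, 0, 1)
    r = evaluate_predictions(truth, prob)
    assert r.dice_loss == pytest.approx(1 - r.dice_coefficient, abs=1e-9)
    hm = 2 * r.precision * r.sensitivity / (r.precision + r.sensitivity)
    assert r.f1 == pytest.approx(hm, abs=1e-9)
    assert list(r.to_dict()) == METRIC_COLUMNS


def test_perfect_prediction_scores_one_everywhere(rng):
    truth = (rng.random((2, 8, 8)) > 0.5).astype(float)
    r = evaluate_predictions(truth, truth)
    for col in ("precision", "sensitivity", "specificity", "f1", "accuracy"):
        assert getattr(r, col) == pytest.approx(1.0)
    assert r.dice_coefficient >= 1 - 1e-5


def test_all_background_degenerate_convention(caplog):
    import logging

    truth = np.zeros((4, 4))
    with caplog.at_level(logging.WARNING):
        r = evaluate_predictions(truth, np.zeros((4, 4)))
    assert r.specificity == 1.0
    assert r.sensitivity == 0.0  # 0/0 reported as 0 with a warning
    assert any("sensitivity" in rec.message for rec in caplog.records)


def test_micro_equals_macro_for_single_image(rng):
    truth = (rng.random((1, 12, 12)) > 0.6).astype(float)
    prob = rng.random((1, 12, 12))
    micro = evaluate_predictions(truth, prob)
    macro = evaluate_predictions(truth, prob, per_image=True)
    for col in METRIC_COLUMNS:
        assert getattr(micro, col) == pytest.approx(getattr(macro, col), abs=1e-12)


# ------------------------------------------------------------------- McNemar

def _brute_force_mcnemar(truth, a, b, correction=True):
    """Enumerate every pixel into the 2x2 concordance table."""
    bb = cc = 0
    for t, pa, pb in zip(truth.ravel(), a.ravel(), b.ravel()):
        ca, cb = pa == t, pb == t
        if ca and not cb:
            bb += 1
        elif cb and not ca:
            cc += 1
    if bb + cc == 0:
        return bb, cc, 0.0
    if correction:
        stat = max(abs(bb - cc) - 1.0, 0.0) ** 2 / (bb + cc)
    else:
        stat = (bb - cc) ** 2 / (bb + cc)
    return bb, cc, stat


def test_mcnemar_identical_models_is_null():
    t = np.zeros((4, 4), dtype=int)
    a = np.eye(4, dtype=int)
    r = mcnemar_pixelwise(t, a, a)
    assert (r.b, r.c, r.statistic, r.p_value) == (0, 0, 0.0, 1.0)


def test_mcnemar_symmetric_discordance_clamps_to_zero():
    truth = np.zeros(10, dtype=int)
    a = np.array([1] * 5 + [0] * 5)
    b = np.array([0] * 5 + [1] * 5)
    r = mcnemar_pixelwise(truth, a, b)
    assert r.b == r.c == 5
    assert r.statistic == 0.0 and r.p_value == 1.0


def test_mcnemar_worked_example_b10_c0():
    truth = np.zeros(30, dtype=int)
    pred_a = np.concatenate([np.zeros(10, dtype=int), np.zeros(20, dtype=int)])
    pred_b = np.concatenate([np.ones(10, dtype=int), np.zeros(20, dtype=int)])
    r = mcnemar_pixelwise(truth, pred_a, pred_b)
    assert (r.b, r.c) == (10, 0)
    assert r.statistic == pytest.approx(8.1)
    assert r.p_value == pytest.approx(0.004427, abs=1e-5)


@pytest.mark.parametrize("correction", [True, False])
def test_mcnemar_matches_pixel_enumeration_oracle(correction, rng):
    truth = (rng.random((16, 16)) > 0.5).astype(int)
    a = (rng.random((16, 16)) > 0.4).astype(int)
    b = (rng.random((16, 16)) > 0.6).astype(int)
    r = mcnemar_pixelwise(truth, a, b, continuity_correction=correction)
    bb, cc, stat = _brute_force_mcnemar(truth, a, b, correction)
    assert (r.b, r.c) == (bb, cc)
    assert r.statistic == pytest.approx(stat, abs=1e-12)


def test_mcnemar_agrees_with_statsmodels(rng):
    sm = pytest.importorskip("statsmodels.stats.contingency_tables")
    truth = (rng.random((16, 16)) > 0.5).astype(int)
    a = (rng.random((16, 16)) > 0.45).astype(int)
    b = (rng.random((16, 16)) > 0.55).astype(int)
    r = mcnemar_pixelwise(truth, a, b)
    n11 = int(np.sum((a == truth) & (b == truth)))
    n00 = int(np.sum((a != truth) & (b != truth)))
    table = [[n11, r.b], [r.c, n00]]
    ref = sm.mcnemar(table, exact=False, correction=True)
    assert r.statistic == pytest.approx(float(ref.statistic), abs=1e-9)
    assert r.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)


def test_mcnemar_swapping_models_exchanges_b_and_c(rng):
    truth = (rng.random(64) > 0.5).astype(int)
    a = (rng.random(64) > 0.5).astype(int)
    b = (rng.random(64) > 0.5).astype(int)
    r1 = mcnemar_pixelwise(truth, a, b)
    r2 = mcnemar_pixelwise(truth, b, a)
    assert (r1.b, r1.c) == (r2.c, r2.b)
    assert r1.statistic == r2.statistic and r1.p_value == r2.p_value


# ---------------------------------------------------------------- Bonferroni

def test_bonferroni_thresholds():
    assert bonferroni_threshold(0.1, 6) == pytest.approx(0.016667, abs=1e-6)
    assert bonferroni_threshold(0.1, 1) == 0.1
    thresholds = [bonferroni_threshold(0.1, m) for m in range(1, 8)]
    assert all(a > b for a, b in zip(thresholds, thresholds[1:]))
    with pytest.raises(ValueError):
        bonferroni_threshold(0.1, 0)


def test_compare_models_matrix_matches_individual_tests(rng):
    truth = (rng.random((2, 8, 8)) > 0.5).astype(int)
    preds = {
        name: (rng.random((2, 8, 8)) > q).astype(int)
        for name, q in [("unet", 0.4), ("sharp", 0.5), ("attn", 0.55), ("both", 0.6)]
    }
    matrix, results = compare_models(truth, preds, alpha=0.1)
    assert len(results) == 6  # C(4,2) pairwise entries
    for (row, col), res in results.items():
        single = mcnemar_pixelwise(truth, preds[col], preds[row])
        assert res.p_value == pytest.approx(single.p_value, abs=1e-12)
        assert matrix.loc[row, col] == pytest.approx(single.p_value, abs=1e-12)
    # strictly lower-triangular in the given model order
    names = list(preds)
    for i, row in enumerate(names):
        for j, col in enumerate(names):
            assert np.isnan(matrix.loc[row, col]) == (i <= j)


def test_compare_models_requires_two(rng):
    with pytest.raises(ValueError):
        compare_models(np.zeros((2, 2), int), {"only": np.zeros((2, 2), int)})


def test_model_compared_with_itself_is_null(rng):
    truth = (rng.random((4, 4)) > 0.5).astype(int)
    pred = (rng.random((4, 4)) > 0.5).astype(int)
    r = mcnemar_pixelwise(truth, pred, pred)
    assert r.p_value == 1.0
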