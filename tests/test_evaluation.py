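"""Confusion metrics, ROC sweep, AUC, operating threshold."""

import math

import numpy as np
import pytest
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score

from vagdx.evaluation import (ConfusionCounts, auc, confusion, evaluate,
                              metrics, operating_threshold, roc_points)


def test_confusion_basic():
    labels = ["OA"] * 3 + ["HC"] * 4
    c = confusion(labels, labels)
    assert (c.tp, c.tn, c.fp, c.fn) == (3, 4, 0, 0)
    flipped = ["HC"] * 3 + ["OA"] * 4
    c2 = confusion(labels, flipped)
    assert (c2.tp, c2.tn) == (0, 0)
    with pytest.raises(ValueError, match="unknown label"):
        confusion(["OA", "XX"], ["OA", "OA"])


def test_metrics_on_published_count_block():
    # 45 controls with 44 correct, 23 OA all correct
    c = ConfusionCounts(tp=23, fp=1, tn=44, fn=0)
    rep = metrics(c)
    assert rep.hc_correct_pct == pytest.approx(97.78, abs=0.005)
    assert rep.oa_correct_pct == 100.0
    assert rep.accuracy_pct == pytest.approx(98.53, abs=0.005)
    assert rep.mcc == pytest.approx(0.968, abs=0.0005)
    assert rep.f1 == pytest.approx(0.979, abs=0.0005)
    assert rep.sensitivity == 1.0
    assert rep.precision == pytest.approx(23 / 24)
    # the HC-positive orientation swaps the asymmetric rates
    assert rep.sensitivity_hc_positive == pytest.approx(44 / 45)
    assert rep.specificity_hc_positive == 1.0


def test_metrics_agree_with_sklearn_on_random_matrices():
    rng = np.random.default_rng(11)
    for _ in range(200):
        tp, fp, tn, fn = rng.integers(0, 30, 4)
        if tp + fp + tn + fn == 0:
            continue
        rep = metrics(ConfusionCounts(tp=int(tp), fp=int(fp), tn=int(tn),
                                      fn=int(fn)))
        y = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        p = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        assert rep.accuracy_pct == pytest.approx(100 * (tp + tn) / len(y))
        if rep.f1 is not None:
            assert rep.f1 == pytest.approx(f1_score(y, p, zero_division=0))
        if rep.mcc is not None:
            assert rep.mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)


def test_mcc_symmetric_under_class_swap():
    rng = np.random.default_rng(12)
    for _ in range(100):
        tp, fp, tn, fn = (int(v) for v in rng.integers(1, 30, 4))
        a = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        b = metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
        assert a.mcc == pytest.approx(b.mcc, abs=1e-12)


def test_undefined_metrics_flagged_not_faked():
    rep = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
    assert rep.precision is None
    assert "precision" in rep.undefined
    with pytest.raises(ValueError):
        metrics(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))


def test_roc_perfect_separation_passes_top_left():
    labels = [0, 0, 0, 1, 1]
    pts = roc_points([0.1, 0.2, 0.3, 0.8, 0.9], labels)
    assert pts[0][:2] == (0.0, 0.0)
    assert pts[-1][:2] == (1.0, 1.0)
    assert any(p[:2] == (0.0, 1.0) for p in pts)
    assert auc(pts) == 1.0


def test_roc_constant_scores_is_diagonal():
    pts = roc_points([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1])
    assert [p[:2] for p in pts] == [(0.0, 0.0), (1.0, 1.0)]
    assert auc(pts) == 0.5


def test_roc_reversed_scores_reflect_curve():
    rng = np.random.default_rng(13)
    s = rng.random(30)
    y = rng.integers(0, 2, 30)
    y[:2] = [0, 1]
    a = auc(roc_points(s, y))
    b = auc(roc_points(-s, y))
    assert a == pytest.approx(1.0 - b, abs=1e-12)


def test_roc_monotone_and_single_class_rejected():
    rng = np.random.default_rng(14)
    pts = roc_points(rng.random(50), rng.integers(0, 2, 50))
    fpr = [p[0] for p in pts]
    tpr = [p[1] for p in pts]
    assert all(b >= a for a, b in zip(fpr, fpr[1:]))
    assert all(b >= a for a, b in zip(tpr, tpr[1:]))
    with pytest.raises(ValueError, match="both classes"):
        roc_points([0.1, 0.2], [1, 1])


def test_auc_equals_concordance_oracle():
    """Trapezoidal AUC == Mann-Whitney concordance (ties count 1/2)."""
    rng = np.random.default_rng(15)
    for _ in range(50):
        n = int(rng.integers(6, 40))
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        s = np.round(rng.random(n), 1)   # coarse scores force ties
        conc = 0.0
        pos, neg = s[y == 1], s[y == 0]
        for sp in pos:
            for sn in neg:
                conc += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        conc /= len(pos) * len(neg)
        a = auc(roc_points(s, y))
        assert a == pytest.approx(conc, abs=1e-12)
        assert a == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_operating_threshold_youden():
    labels = [0, 0, 1, 1]
    thr = operating_threshold(roc_points([0.05, 0.1, 0.9, 0.95], labels))
    assert 0.1 < thr <= 0.9
    # degenerate: constant scores -> J = 0 everywhere, largest threshold wins
    pts = roc_points([0.4, 0.4, 0.4, 0.4], labels)
    assert operating_threshold(pts) == 0.4
    rng = np.random.default_rng(16)
    s, y = rng.random(30), rng.integers(0, 2, 30)
    y[:2] = [0, 1]
    pts = roc_points(s, y)
    best = operating_threshold(pts)
    j = {t: tpr - fpr for fpr, tpr, t in pts if math.isfinite(t)}
    assert j[best] == max(j.values())


def test_evaluate_full_report():
    rep = evaluate(["HC", "HC", "OA", "OA"], [0.1, 0.6, 0.7, 0.9])
    assert rep.counts == {"tp": 2, "fp": 1, "tn": 1, "fn": 0}
    assert rep.auc == 1.0
    assert rep.roc_threshold == pytest.approx(0.7)
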