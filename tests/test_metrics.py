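"""Metric implementations against brute-force oracles."""

import numpy as np
import pytest

from ecgtl.metrics import (confusion_counts, f_beta_g_beta, f_max, macro_f1,
                           mean_classwise_auc, threshold_search)


def _brute_f1(y_true, y_pred, cls):
    tp = sum(t == cls and p == cls for t, p in zip(y_true, y_pred))
    fp = sum(t != cls and p == cls for t, p in zip(y_true, y_pred))
    fn = sum(t == cls and p != cls for t, p in zip(y_true, y_pred))
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def _brute_auc(y, s):
    """Exhaustive positive-negative pair counting with half credit for ties."""
    pos = [x for x, t in zip(s, y) if t]
    neg = [x for x, t in zip(s, y) if not t]
    total = wins = 0
    for p in pos:
        for n in neg:
            total += 1
            wins += (p > n) + 0.5 * (p == n)
    return wins / total


def test_macro_f1_hand_examples():
    assert macro_f1(list("AABB"), list("AABB"))[0] == 1.0
    macro, per = macro_f1(list("AABB"), list("ABAB"))
    assert per == {"A": 0.5, "B": 0.5}
    assert macro == 0.5
    # all predictions one class on balanced 4-class truth
    truth = list("ABCD") * 5
    pred = ["A"] * 20
    macro, per = macro_f1(truth, pred)
    assert per["A"] == pytest.approx(2 * 5 / (2 * 5 + 15))
    assert macro == pytest.approx(per["A"] / 4)


def test_macro_f1_matches_confusion_oracle_on_random_instances():
    rng = np.random.default_rng(0)
    classes = list("ABCD")
    for _ in range(200):
        n = int(rng.integers(2, 30))
        yt = rng.choice(classes, n)
        yp = rng.choice(classes, n)
        macro, per = macro_f1(yt, yp, classes=classes)
        expect = [_brute_f1(yt, yp, c) for c in classes]
        assert macro == pytest.approx(np.mean(expect))
        for c, e in zip(classes, expect):
            assert per[c] == pytest.approx(e)


def test_macro_f1_rejects_empty_input():
    with pytest.raises(ValueError):
        macro_f1([], [])


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(1)
    for _ in range(100):
        n = int(rng.integers(4, 50))
        y = rng.integers(0, 2, (n, 3))
        s = np.round(rng.random((n, 3)), 1)  # coarse scores force ties
        cols = [j for j in range(3) if 0 < y[:, j].sum() < n]
        if not cols:
            continue
        expect = np.mean([_brute_auc(y[:, j], s[:, j]) for j in cols])
        assert mean_classwise_auc(y, s) == pytest.approx(expect)


def test_auc_degenerate_cases():
    y = np.array([[1], [0], [1], [0]])
    assert mean_classwise_auc(y, np.array([[.9], [.1], [.8], [.2]])) == 1.0
    assert mean_classwise_auc(y, np.full((4, 1), 0.5)) == 0.5
    with pytest.raises(ValueError):
        mean_classwise_auc(np.ones((3, 1)), np.random.rand(3, 1))


def test_f_max_hand_cases():
    y = np.array([[1, 0, 1], [0, 1, 0]])
    assert f_max(y, y.astype(float)) == 1.0
    # one sample, truth {a, b}, predicted {a}: P=1, R=0.5, F=2/3
    y1 = np.array([[1, 1, 0]])
    s1 = np.array([[0.9, 0.1, 0.0]])
    assert f_max(y1, s1, grid=np.array([0.5])) == pytest.approx(2 / 3)


def test_f_max_nondecreasing_under_grid_refinement():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, (20, 4))
    y[y.sum(axis=1) == 0, 0] = 1
    s = rng.random((20, 4))
    coarse = f_max(y, s, grid=np.arange(0, 1.01, 0.2))
    fine = f_max(y, s, grid=np.arange(0, 1.01, 0.05))
    assert fine >= coarse


def test_f_beta_g_beta_hand_cases():
    y = np.array([[1, 0], [0, 1]])
    assert f_beta_g_beta(y, y) == (1.0, 1.0)
    # one class: TP=1, FN=1, FP=0, beta=2
    y1 = np.array([[1], [1]])
    p1 = np.array([[1], [0]])
    fb, gb = f_beta_g_beta(y1, p1)
    assert fb == pytest.approx(5 / 9)
    assert gb == pytest.approx(1 / 3)
    fb0, gb0 = f_beta_g_beta(y1, np.zeros_like(y1))
    assert fb0 == 0.0 and gb0 == 0.0


def test_f_beta_g_beta_matches_direct_formula_on_random_instances():
    rng = np.random.default_rng(3)
    for _ in range(100):
        y = rng.integers(0, 2, (15, 3))
        p = rng.integers(0, 2, (15, 3))
        fb, gb = f_beta_g_beta(y, p)
        fs, gs = [], []
        for j in range(3):
            c = confusion_counts(y[:, j], p[:, j])
            fden = 5 * c.tp + c.fp + 4 * c.fn
            gden = c.tp + c.fp + 2 * c.fn
            fs.append(5 * c.tp / fden if fden else 0.0)
            gs.append(c.tp / gden if gden else 0.0)
        assert fb == pytest.approx(np.mean(fs))
        assert gb == pytest.approx(np.mean(gs))


def test_threshold_search_returns_smallest_argmax():
    y = np.array([[1], [1], [0], [0]])
    s = np.array([[0.8], [0.7], [0.2], [0.1]])
    t = threshold_search(y, s, lambda yt, yp: f_beta_g_beta(yt, yp)[0],
                         grid=np.arange(0, 1.01, 0.1))
    # any threshold in (0.2, 0.7] is perfect; smallest grid point wins
    assert t == pytest.approx(0.3)
    assert threshold_search(y, s, lambda yt, yp: f_beta_g_beta(yt, yp)[0],
                            grid=np.array([0.42])) == pytest.approx(0.42)


def test_metrics_invariant_to_sample_order():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, (25, 3))
    y[y.sum(axis=1) == 0, 1] = 1
    s = rng.random((25, 3))
    perm = rng.permutation(25)
    assert mean_classwise_auc(y, s) == pytest.approx(
        mean_classwise_auc(y[perm], s[perm]))
    assert f_max(y, s) == pytest.approx(f_max(y[perm], s[perm]))
    assert f_beta_g_beta(y, s > 0.5) == f_beta_g_beta(y[perm], s[perm] > 0.5)
    yt = rng.choice(list("AB"), 25)
    yp = rng.choice(list("AB"), 25)
    assert macro_f1(yt, yp)[0] == pytest.approx(macro_f1(yt[perm], yp[perm])[0])
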