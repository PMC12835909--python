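"""Agreement statistics, split plans, SVM experiment and confusion metrics."""

import numpy as np
import pytest
from scipy import stats as sstats

from pdfecg.errors import (
    DegenerateInputError,
    PairingError,
    ShapeError,
    StratificationError,
)
from pdfecg.evaluate import (
    bland_altman,
    make_split_plan,
    metrics_from_confusion,
    pearson_test,
    train_eval,
)


# ---------------------------------------------------------------------------
# Bland-Altman

def test_identical_series_zero_width_limits(rng):
    x = rng.normal(size=20)
    res = bland_altman(x, x)
    assert res.bias == 0.0
    assert res.loa_low == res.loa_high == 0.0
    assert res.pearson_r == pytest.approx(1.0)


def test_constant_offset_pair():
    res = bland_altman(np.array([1.0, 2, 3]), np.array([2.0, 3, 4]))
    np.testing.assert_allclose(res.diffs, [-1, -1, -1])
    assert res.bias == pytest.approx(-1.0)
    assert res.loa_low == res.loa_high == pytest.approx(-1.0)


def test_simulation_recovers_noise_limits(rng):
    truth = rng.uniform(100, 200, size=1000)
    noisy = truth + rng.normal(0, 4.0, size=1000)
    res = bland_altman(noisy, truth)
    assert abs(res.bias) < 0.4
    width = res.loa_high - res.loa_low
    assert width == pytest.approx(2 * 1.96 * 4.0, rel=0.10)


def test_mismatched_lengths_rejected():
    with pytest.raises(PairingError):
        bland_altman(np.arange(5.0), np.arange(6.0))


# ---------------------------------------------------------------------------
# Pearson test

def test_perfect_linear_relation():
    x = np.arange(10.0)
    r, p, reject = pearson_test(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert reject


def test_perfect_anticorrelation():
    x = np.arange(10.0)
    r, _, _ = pearson_test(x, -x)
    assert r == pytest.approx(-1.0)


def test_matches_brute_force_formula():
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 6])
    r, p, _ = pearson_test(x, y)
    # direct covariance computation, no shortcuts
    brute = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert r == pytest.approx(brute, abs=1e-12)
    # scipy as an independent oracle for the p value
    sp = sstats.pearsonr(x, y)
    assert r == pytest.approx(sp.statistic, abs=1e-12)
    assert p == pytest.approx(sp.pvalue, abs=1e-12)


def test_random_vectors_match_scipy(rng):
    for _ in range(25):
        n = int(rng.integers(4, 40))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        r, p, _ = pearson_test(x, y)
        sp = sstats.pearsonr(x, y)
        assert r == pytest.approx(sp.statistic, abs=1e-10)
        assert p == pytest.approx(sp.pvalue, abs=1e-10)


def test_zero_variance_rejected():
    with pytest.raises(DegenerateInputError):
        pearson_test(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# split plan

def _cohort_labels(n_per_class=6, classes=("a", "b", "c", "d", "e")):
    return {f"{c}{i}": c for c in classes for i in range(n_per_class)}


def test_every_test_set_one_patient_per_class():
    plan = make_split_plan(_cohort_labels(), n_runs=100, seed=1)
    labels = _cohort_labels()
    for train, test in plan.runs:
        assert len(test) == 5
        assert sorted(labels[p] for p in test) == sorted(plan.classes)
        assert set(train) & set(test) == set()
        assert len(train) + len(test) == len(labels)


def test_same_seed_identical_plan():
    a = make_split_plan(_cohort_labels(), 50, seed=9)
    b = make_split_plan(_cohort_labels(), 50, seed=9)
    assert a.runs == b.runs


def test_patient_selection_roughly_uniform():
    labels = _cohort_labels(n_per_class=10)
    plan = make_split_plan(labels, n_runs=100, seed=2)
    counts = {p: 0 for p in labels}
    for _, test in plan.runs:
        for p in test:
            counts[p] += 1
    for c in set(labels.values()):
        members = [counts[p] for p in labels if labels[p] == c]
        assert sum(members) == 100
        chi2 = sum((m - 10) ** 2 / 10 for m in members)
        assert sstats.chi2.sf(chi2, df=9) > 0.01


def test_class_with_one_patient_rejected():
    labels = {"a0": "a", "a1": "a", "b0": "b"}
    with pytest.raises(StratificationError):
        make_split_plan(labels, 10, seed=0)


# ---------------------------------------------------------------------------
# confusion-matrix metrics

def test_perfect_confusion_all_ones():
    m = metrics_from_confusion(np.eye(4, dtype=int) * 7)
    for i in range(4):
        assert m[i] == {"precision": 1.0, "sensitivity": 1.0,
                        "specificity": 1.0, "f1": 1.0}


def test_two_class_hand_computed():
    m = metrics_from_confusion([[8, 2], [1, 9]])
    assert m[0]["precision"] == pytest.approx(8 / 9, abs=1e-12)
    assert m[0]["sensitivity"] == pytest.approx(0.8, abs=1e-12)
    assert m[0]["specificity"] == pytest.approx(0.9, abs=1e-12)
    f1 = 2 * (8 / 9) * 0.8 / (8 / 9 + 0.8)
    assert m[0]["f1"] == pytest.approx(f1, abs=1e-12)


def test_zero_row_flagged():
    m = metrics_from_confusion([[0, 0], [3, 5]])
    assert m[0]["sensitivity"] == 0.0
    assert any("sensitivity" in f for f in m["_flags"])


def test_non_square_rejected():
    with pytest.raises(ShapeError):
        metrics_from_confusion(np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# SVM experiment on tiny synthetic feature clouds

def _blob_cohort(rng, n_per_class=4, n_ecgs=3, spread=0.05, classes=5):
    centers = rng.normal(size=(classes, 8)) * 3.0
    X, y, pats = [], [], []
    for c in range(classes):
        for p in range(n_per_class):
            pid = f"c{c}p{p}"
            for _ in range(n_ecgs):
                X.append(centers[c] + rng.normal(0, spread, size=8))
                y.append(f"class{c}")
                pats.append(pid)
    return np.array(X), np.array(y), np.array(pats)


def test_separable_blobs_high_recall(rng):
    X, y, pats = _blob_cohort(rng)
    plan = make_split_plan(dict(zip(pats, y)), n_runs=20, seed=3)
    res = train_eval(X, y, pats, plan, probability=False)
    for c in res.classes:
        assert res.per_class[c]["sensitivity"] > 0.9
    # confusion conservation: 20 runs x 5 patients x 3 ECGs
    assert res.confusion.sum() == 20 * 5 * 3


def test_auc_antisymmetry_under_score_negation(rng):
    from sklearn.metrics import roc_auc_score
    scores = rng.normal(size=200)
    labels = (rng.random(200) < 0.4).astype(int)
    auc = roc_auc_score(labels, scores)
    assert roc_auc_score(labels, -scores) == pytest.approx(1 - auc, abs=1e-12)


def test_patient_leakage_impossible(rng):
    X, y, pats = _blob_cohort(rng)
    plan = make_split_plan(dict(zip(pats, y)), n_runs=30, seed=4)
    for train, test in plan.runs:
        assert not set(train) & set(test)
    # an ECG-level check too: every ECG of a test patient is tested together
    res = train_eval(X, y, pats, plan, probability=False)
    per_run_tests = res.confusion.sum() / plan.n_runs
    assert per_run_tests == 5 * 3


def test_exchangeable_classes_split_symmetrically(rng):
    """Two classes drawn from one distribution confuse ~50/50 with each other."""
    X, y, pats = [], [], []
    for c, label in enumerate(["u", "v"]):
        for p in range(8):
            pid = f"{label}{p}"
            for _ in range(3):
                X.append(rng.normal(size=6))          # identical by construction
                y.append(label)
                pats.append(pid)
    X = np.array(X)
    plan = make_split_plan(dict(zip(pats, y)), n_runs=60, seed=5)
    res = train_eval(X, np.array(y), np.array(pats), plan, probability=False)
    total = res.confusion.sum(axis=1)
    frac_correct = np.diag(res.confusion) / total
    assert np.all(np.abs(frac_correct - 0.5) < 0.15)
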