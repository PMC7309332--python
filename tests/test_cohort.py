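"""ROC/AUC/bootstrap/Youden against brute-force oracles and sklearn."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sstwin import (
    LabeledCohort,
    auc,
    bootstrap_ci,
    evaluate_cohort,
    roc_curve,
    youden_cutoff,
)
from sstwin.errors import DegenerateCohortError


def pairwise_auc(scores, labels):
    """Brute-force Mann-Whitney concordance over all positive x negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def confusion_point(scores, labels, thr):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    sens = sum(s >= thr for s in pos) / len(pos)
    spec = sum(s < thr for s in neg) / len(neg)
    return sens, spec


def test_single_class_rejected():
    with pytest.raises(DegenerateCohortError):
        auc(LabeledCohort(scores=np.arange(5.0), labels=np.ones(5)))
    with pytest.raises(DegenerateCohortError):
        roc_curve(LabeledCohort(scores=np.arange(5.0), labels=np.zeros(5)))


def test_perfect_separation():
    c = LabeledCohort(scores=np.array([3.0, 4.0, 1.0, 2.0]), labels=np.array([1, 1, 0, 0]))
    assert auc(c) == 1.0
    curve = roc_curve(c)
    assert any(s == 1.0 and p == 1.0 for _, s, p in curve)
    cut, sens, spec = youden_cutoff(c)
    assert (sens, spec) == (1.0, 1.0)
    assert 2.0 < cut <= 3.0


def test_all_ties_uninformative():
    c = LabeledCohort(scores=np.full(8, 5.0), labels=np.array([1, 1, 1, 1, 0, 0, 0, 0]))
    assert auc(c) == 0.5
    curve = roc_curve(c)
    np.testing.assert_allclose(curve[:, 1] + curve[:, 2], 1.0)
    cut, _, _ = youden_cutoff(c)
    assert cut == curve[:, 0].min()  # tie-break toward the smallest threshold


@pytest.mark.parametrize("seed", range(10))
def test_roc_points_match_confusion_counts(seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(size=20), 1)  # rounding forces some ties
    labels = np.concatenate([np.ones(10), np.zeros(10)])
    c = LabeledCohort(scores=scores, labels=labels)
    for thr, sens, spec in roc_curve(c):
        e_sens, e_spec = confusion_point(scores, labels, thr)
        assert sens == pytest.approx(e_sens, abs=1e-12)
        assert spec == pytest.approx(e_spec, abs=1e-12)


@pytest.mark.parametrize("seed", range(30))
def test_auc_equals_pairwise_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 21))
    n_pos = int(rng.integers(1, n))
    scores = rng.integers(0, 6, n).astype(float)  # heavy ties
    labels = np.zeros(n)
    labels[rng.choice(n, n_pos, replace=False)] = 1
    c = LabeledCohort(scores=scores, labels=labels)
    assert auc(c) == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)


def test_auc_cross_checked_against_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(42)
    scores = rng.normal(size=60) + np.repeat([1.0, 0.0], 30)
    labels = np.repeat([1, 0], 30)
    c = LabeledCohort(scores=scores, labels=labels)
    assert auc(c) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_trapezoid_area_equals_auc():
    rng = np.random.default_rng(11)
    scores = np.round(rng.normal(size=40), 1)
    labels = np.concatenate([np.ones(25), np.zeros(15)])
    c = LabeledCohort(scores=scores, labels=labels)
    curve = roc_curve(c)  # thresholds ascending -> fpr/tpr descending along the curve
    order = np.argsort(-curve[:, 0], kind="stable")
    fpr = 1.0 - curve[order, 2]
    tpr = curve[order, 1]
    area = np.trapezoid(tpr, fpr)
    assert abs(area - auc(c)) <= 1e-12


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(0, 10_000))
def test_label_flip_symmetry(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=16)  # continuous: ties almost surely absent
    labels = np.concatenate([np.ones(8), np.zeros(8)])
    c = LabeledCohort(scores=scores, labels=labels)
    flipped = LabeledCohort(scores=-scores, labels=1 - labels)
    assert auc(flipped) == pytest.approx(auc(c), abs=1e-12)
    negated = LabeledCohort(scores=-scores, labels=labels)
    assert auc(negated) == pytest.approx(1.0 - auc(c), abs=1e-12)


def test_bootstrap_deterministic_for_fixed_seed():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=68) + np.concatenate([np.full(45, 0.8), np.zeros(23)])
    labels = np.concatenate([np.ones(45), np.zeros(23)])
    c = LabeledCohort(scores=scores, labels=labels)
    assert bootstrap_ci(c, n_boot=200, seed=7) == bootstrap_ci(c, n_boot=200, seed=7)


def test_bootstrap_perfect_separation_interval():
    scores = np.concatenate([np.arange(20) + 100.0, np.arange(20)])
    labels = np.concatenate([np.ones(20), np.zeros(20)])
    c = LabeledCohort(scores=scores, labels=labels)
    assert bootstrap_ci(c, n_boot=200, seed=0) == (1.0, 1.0)


def test_bootstrap_brackets_point_auc():
    rng = np.random.default_rng(12)
    scores = np.concatenate([rng.normal(1.0, 1.0, 45), rng.normal(0.0, 1.0, 23)])
    labels = np.concatenate([np.ones(45), np.zeros(23)])
    c = LabeledCohort(scores=scores, labels=labels)
    lo, hi = bootstrap_ci(c, n_boot=500, seed=3)
    assert lo <= auc(c) <= hi


def test_bootstrap_ci_narrows_with_sample_size():
    def width(n, seed):
        rng = np.random.default_rng(seed)
        scores = np.concatenate([rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n)])
        labels = np.concatenate([np.ones(n), np.zeros(n)])
        lo, hi = bootstrap_ci(LabeledCohort(scores=scores, labels=labels), n_boot=300, seed=seed)
        return hi - lo

    assert width(300, 21) < width(30, 21)


def test_youden_matches_exhaustive_search():
    scores = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    labels = np.array([0, 0, 1, 0, 1, 1, 0, 1])
    c = LabeledCohort(scores=scores, labels=labels)
    best_j, best_thr = -np.inf, None
    for thr in sorted(set(scores) | {0.0, 8.0}):
        sens, spec = confusion_point(scores, labels, thr)
        if sens + spec - 1 > best_j + 1e-12:
            best_j, best_thr = sens + spec - 1, thr
    cut, sens, spec = youden_cutoff(c)
    assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)
    e_sens, e_spec = confusion_point(scores, labels, cut)
    assert (sens, spec) == (e_sens, e_spec)


def test_evaluate_cohort_summary_consistent():
    rng = np.random.default_rng(8)
    scores = np.concatenate([rng.normal(1.0, 1.0, 45), rng.normal(0.0, 1.0, 23)])
    labels = np.concatenate([np.ones(45), np.zeros(23)])
    c = LabeledCohort(scores=scores, labels=labels)
    s = evaluate_cohort(c, n_boot=200, seed=1)
    assert 0.0 <= s.ci_low <= s.ci_high <= 1.0
    e_sens, e_spec = confusion_point(scores, labels, s.cutoff)
    assert s.sensitivity == pytest.approx(e_sens) and s.specificity == pytest.approx(e_spec)
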