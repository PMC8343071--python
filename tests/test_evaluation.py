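"""Evaluation metrics: confusion counts, P/R/F conventions, ROC and PR areas."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpair import (CASE, CONTROL, ConfigurationError, MiRPSModel,
                     SyntheticConfig, confusion_counts, evaluate,
                     generate_dataset, pr_auc, precision_recall_fscore,
                     roc_auc)


def labelize(binary):
    return np.array([CASE if v else CONTROL for v in binary], dtype=object)


def roc_auc_oracle(scores, y):
    """Pairwise Mann-Whitney count with half-weight ties."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[y == 1], scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def pr_auc_oracle(scores, y):
    """Exhaustive step-sum of (R_i - R_{i-1}) * P_i over descending thresholds."""
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (y == 1)).sum())
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


# ---------------------------------------------------------------------------
# confusion counts and P/R/F
# ---------------------------------------------------------------------------

def test_confusion_counts_perfect_predictions():
    truth = labelize([1] * 5 + [0] * 5)
    assert confusion_counts(truth, truth) == (5, 0, 5, 0)


def test_confusion_counts_all_control_predictions():
    truth = labelize([1] * 3 + [0] * 4)
    pred = labelize([0] * 7)
    assert confusion_counts(pred, truth) == (0, 0, 4, 3)


def test_confusion_counts_mixed():
    pred = labelize([1, 1, 0])
    truth = labelize([1, 0, 0])
    assert confusion_counts(pred, truth) == (1, 1, 1, 0)


def test_confusion_counts_length_mismatch():
    with pytest.raises(ConfigurationError, match="length"):
        confusion_counts(labelize([1, 0]), labelize([1, 0, 0]))


def test_precision_recall_fscore_symmetric_case():
    assert precision_recall_fscore(9, 1, 0, 1) == (0.9, 0.9, pytest.approx(0.9))


def test_zero_denominator_conventions():
    assert precision_recall_fscore(0, 0, 10, 5) == (0.0, 0.0, 0.0)


def test_fscore_from_published_style_counts():
    # a synthetic confusion matrix whose precision is exactly 0.9239
    precision, recall, f = precision_recall_fscore(tp=9239, fp=761, tn=9000,
                                                   fn=761)
    assert precision == pytest.approx(0.9239, abs=1e-12)
    assert recall == pytest.approx(0.9239, abs=1e-12)
    assert f == pytest.approx(0.9239, abs=1e-12)


@settings(deadline=None, max_examples=100)
@given(tp=st.integers(0, 500), fp=st.integers(0, 500),
       tn=st.integers(0, 500), fn=st.integers(0, 500))
def test_fscore_is_harmonic_mean_bounded(tp, fp, tn, fn):
    precision, recall, f = precision_recall_fscore(tp, fp, tn, fn)
    assert 0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0 and 0.0 <= f <= 1.0
    if precision > 0 and recall > 0:
        eps = 1e-9
        assert min(precision, recall) - eps <= f <= max(precision, recall) + eps


# ---------------------------------------------------------------------------
# ROC AUC
# ---------------------------------------------------------------------------

def test_roc_auc_perfect_separation():
    y = np.repeat([1, 0], 10)
    scores = np.concatenate([np.arange(10, 20), np.arange(10)])
    assert roc_auc(scores, labelize(y)) == 1.0


def test_roc_auc_equals_pairwise_oracle_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(10):
        y = rng.integers(0, 2, size=30)
        if y.min() == y.max():
            continue
        scores = rng.integers(0, 6, size=30).astype(float)  # many ties
        assert roc_auc(scores, labelize(y)) == pytest.approx(
            roc_auc_oracle(scores, y))


def test_roc_auc_random_scores_near_half():
    rng = np.random.default_rng(42)
    n = 2000
    y = np.repeat([1, 0], n // 2)
    scores = rng.normal(size=n)
    se = np.sqrt((n / 2 + n / 2 + 1) / (12 * (n / 2) * (n / 2)))
    assert abs(roc_auc(scores, labelize(y)) - 0.5) < 3 * se


def test_roc_auc_antisymmetry():
    rng = np.random.default_rng(1)
    y = np.repeat([1, 0], 25)
    scores = rng.normal(size=50)
    a = roc_auc(scores, labelize(y))
    assert roc_auc(-scores, labelize(y)) == pytest.approx(1.0 - a)


def test_roc_auc_monotone_transform_invariance():
    rng = np.random.default_rng(2)
    y = np.repeat([1, 0], 20)
    scores = rng.normal(size=40)
    a = roc_auc(scores, labelize(y))
    assert roc_auc(np.exp(scores), labelize(y)) == pytest.approx(a)


def test_roc_auc_single_class_is_an_error():
    with pytest.raises(ConfigurationError, match="both classes"):
        roc_auc([1.0, 2.0], labelize([1, 1]))


# ---------------------------------------------------------------------------
# PR AUC
# ---------------------------------------------------------------------------

def test_pr_auc_perfect_separation():
    y = np.repeat([1, 0], 10)
    scores = np.concatenate([np.arange(10, 20), np.arange(10)])
    assert pr_auc(scores, labelize(y)) == pytest.approx(1.0, abs=1e-12)


def test_pr_auc_matches_threshold_sweep_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        y = rng.integers(0, 2, size=40)
        if y.sum() == 0:
            continue
        scores = rng.normal(size=40)
        assert pr_auc(scores, labelize(y)) == pytest.approx(
            pr_auc_oracle(scores, y))


def test_pr_auc_random_scores_near_prevalence():
    rng = np.random.default_rng(4)
    n, prevalence = 4000, 0.2
    y = (np.arange(n) < prevalence * n).astype(int)
    scores = rng.normal(size=n)
    assert pr_auc(scores, labelize(y)) == pytest.approx(prevalence, abs=0.03)


def test_pr_auc_without_positives_is_an_error():
    with pytest.raises(ConfigurationError, match="positive"):
        pr_auc([1.0, 2.0], labelize([0, 0]))


def test_perfect_ranking_maximizes_both_areas_together():
    y = labelize(np.repeat([1, 0], 8))
    good = np.concatenate([np.arange(8, 16), np.arange(8)]).astype(float)
    assert roc_auc(good, y) == 1.0
    assert pr_auc(good, y) == pytest.approx(1.0, abs=1e-12)
    good[0] = -1.0  # break the separation
    assert roc_auc(good, y) < 1.0 and pr_auc(good, y) < 0.999


# ---------------------------------------------------------------------------
# end-to-end evaluate
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted_model_and_data():
    cfg = SyntheticConfig(n_case=120, n_control=120, n_features=30,
                          n_planted_pairs=4, fidelity=0.99, seed=31)
    model = MiRPSModel(pairs=tuple(cfg.planted_pairs),
                       coefficients=(3.0, 3.0, 3.0, 3.0), intercept=-6.0)
    fresh = generate_dataset(dataclasses.replace(cfg, seed=32))
    return model, fresh


def test_evaluate_high_fidelity_signature(planted_model_and_data):
    model, fresh = planted_model_and_data
    report = evaluate(model, fresh)
    assert report.roc_auc > 0.99
    assert report.pr_auc > 0.99
    assert report.n_samples == fresh.n_samples


def test_evaluate_perfectly_separable_fixture():
    cfg = SyntheticConfig(n_case=40, n_control=40, n_features=10,
                          n_planted_pairs=2, fidelity=1.0, seed=33)
    data = generate_dataset(cfg)
    model = MiRPSModel(pairs=tuple(cfg.planted_pairs),
                       coefficients=(5.0, 5.0), intercept=-5.0)
    report = evaluate(model, data)
    assert report.f_score == 1.0
    assert (report.tp, report.fp, report.tn, report.fn) == (40, 0, 40, 0)


def test_evaluate_shuffled_labels_near_chance(planted_model_and_data):
    model, fresh = planted_model_and_data
    rng = np.random.default_rng(5)
    shuffled = fresh.subset_samples(np.ones(fresh.n_samples, dtype=bool))
    shuffled.labels = rng.permutation(fresh.labels)
    report = evaluate(model, shuffled)
    n = fresh.n_samples // 2
    se = np.sqrt((2 * n + 1) / (12 * n * n))
    assert abs(report.roc_auc - 0.5) < 3 * se
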