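"""AUC/BAC metrics, fold construction and the optimism correction."""

import numpy as np
import pandas as pd
import pytest

from urispec import (CohortConfig, balanced_accuracy, correct_metric,
                     cv_optimism, generate_cohort, make_folds, roc_auc,
                     single_band_marker, snv)
from urispec.evaluation import CVReport, PerformanceMetrics, roc_coordinates
from urispec.exceptions import DegenerateOutcomeError, EvaluationError


def sweep_auc(scores, labels):
    """Brute-force oracle: trapezoid over the exhaustive threshold sweep."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1], [-np.inf]])
    pts = []
    for t in thresholds:
        pred = scores >= t
        tpr = np.sum(pred & (labels == 1)) / labels.sum()
        fpr = np.sum(pred & (labels == 0)) / (labels == 0).sum()
        pts.append((fpr, tpr))
    pts = np.array(sorted(set(pts)))
    return np.trapezoid(pts[:, 1], pts[:, 0])


# ---------------------------------------------------------------------------
# AUC

def test_perfectly_ranked_scores_give_auc_one():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0


def test_auc_equals_threshold_sweep_on_tied_fixture():
    scores = np.array([0.2, 0.4, 0.4, 0.6, 0.8, 0.8])
    labels = np.array([0, 0, 1, 0, 1, 1])
    assert roc_auc(scores, labels) == pytest.approx(sweep_auc(scores, labels),
                                                    abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_auc_equals_threshold_sweep_random_tied(seed):
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 5, size=30) / 4.0  # many ties
    labels = rng.integers(0, 2, size=30)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert roc_auc(scores, labels) == pytest.approx(sweep_auc(scores, labels),
                                                    abs=1e-12)


def test_independent_scores_give_half(rng):
    labels = rng.integers(0, 2, size=10_000)
    scores = rng.random(10_000)
    assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.random(500)
    labels = rng.integers(0, 2, size=500)
    a = roc_auc(scores, labels)
    assert roc_auc(np.exp(5 * scores), labels) == pytest.approx(a, abs=1e-12)
    assert roc_auc(np.log(scores + 1e-9), labels) == pytest.approx(a, abs=1e-12)


def test_single_class_labels_raise():
    with pytest.raises(DegenerateOutcomeError):
        roc_auc([0.2, 0.8], [1, 1])


# ---------------------------------------------------------------------------
# balanced accuracy

def test_perfect_scores_give_bac_one():
    m = balanced_accuracy([0.1, 0.9, 0.2, 0.8], [0, 1, 0, 1])
    assert m.bac == 1.0 and m.sensitivity == 1.0 and m.specificity == 1.0


def test_all_negative_predictions_give_half():
    m = balanced_accuracy([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1])
    assert m.sensitivity == 0.0 and m.specificity == 1.0 and m.bac == 0.5


def test_printed_confusion_fixture():
    """TP=3 FN=1 TN=4 FP=2 -> BAC = (0.75 + 2/3)/2."""
    labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    scores = [0.9, 0.8, 0.7, 0.1, 0.2, 0.3, 0.1, 0.2, 0.9, 0.8]
    m = balanced_accuracy(scores, labels)
    assert m.sensitivity == pytest.approx(0.75)
    assert m.specificity == pytest.approx(4 / 6)
    assert m.bac == pytest.approx((0.75 + 4 / 6) / 2)


# ---------------------------------------------------------------------------
# folds

def test_401_samples_split_into_81_80_80_80_80():
    a = make_folds(401, 5, seed=0)
    sizes = sorted(np.bincount(a), reverse=True)
    assert sizes == [81, 80, 80, 80, 80]


def test_ten_samples_five_folds_all_size_two():
    assert sorted(np.bincount(make_folds(10, 5, seed=1))) == [2] * 5


def test_folds_deterministic_and_exhaustive():
    a = make_folds(100, 5, seed=9)
    b = make_folds(100, 5, seed=9)
    np.testing.assert_array_equal(a, b)
    assert set(a) == set(range(5)) and a.size == 100


def test_too_few_samples_raises():
    with pytest.raises(ValueError):
        make_folds(3, 5, seed=0)


# ---------------------------------------------------------------------------
# optimism correction

def test_correct_metric_reproduces_worked_arithmetic():
    assert correct_metric(0.771, 0.060) == pytest.approx(0.711)
    assert correct_metric(0.947, 0.026) == pytest.approx(0.921)
    assert correct_metric(0.5, 0.0) == 0.5


def _pm(auc, bac):
    return PerformanceMetrics(auc=auc, bac=bac, sensitivity=bac,
                              specificity=bac, threshold=0.5)


def test_correction_term_is_mean_of_fold_differences():
    diffs = [0.05, 0.07, 0.06, 0.05, 0.07]
    inner = [_pm(0.9, 0.8 + d) for d in diffs]
    outer = [_pm(0.9, 0.8) for _ in diffs]
    rep = CVReport(marker="m", kind="lr", k=5, seed=0,
                   fold_assignment=np.zeros(10, int), inner=inner, outer=outer,
                   fold_features=[()] * 5, global_inner=_pm(0.9, 0.85),
                   global_selection=None)
    assert rep.correction_bac == pytest.approx(0.06)
    assert rep.corrected_bac == pytest.approx(0.85 - 0.06)
    assert rep.correction_auc == pytest.approx(0.0)


def test_strong_signal_has_negligible_optimism():
    """Near-separable marker: inner ~ out-of-sample, correction ~ 0."""
    cohort = generate_cohort(
        CohortConfig(n_patients=150, samples_per_patient_dist=2, seed=4),
        [single_band_marker(healthy_fraction=0.6)])
    S = snv(cohort.spectra[("DT", "low")])
    ch = cohort.grid.nearest_channel(426.0)
    X = pd.DataFrame({"band": S[:, ch]})
    y = cohort.truth["single_band_class"].to_numpy()
    rep = cv_optimism(X, y, groups=cohort.patient_ids, kind="lr", seed=0)
    assert rep.global_inner.auc > 0.9
    assert abs(rep.correction_auc) < 0.03
    assert abs(rep.corrected_auc - rep.global_inner.auc) < 0.03


def test_fold_rebuild_on_rare_class(rng):
    """7 positives in 60: folds are redrawn until every one is mixed."""
    y = np.zeros(60, int)
    y[:7] = 1
    X = pd.DataFrame({"x": rng.normal(size=60)})
    rep = cv_optimism(X, y, kind="lr", k=5, seed=0)
    for fold in range(5):
        assert y[rep.fold_assignment == fold].sum() >= 1


def test_unsplittable_outcome_raises_evaluation_error(rng):
    y = np.zeros(10, int)
    y[0] = 1  # one positive cannot reach all 5 test folds
    X = pd.DataFrame({"x": rng.normal(size=10)})
    with pytest.raises(EvaluationError):
        cv_optimism(X, y, kind="lr", k=5, seed=0)


def test_bac_identity_holds_in_cv_report():
    cohort = generate_cohort(
        CohortConfig(n_patients=80, samples_per_patient_dist=2, seed=2),
        [single_band_marker(healthy_fraction=0.6)])
    S = snv(cohort.spectra[("AT", "low")])
    X = pd.DataFrame({"f": S[:, cohort.grid.nearest_channel(426.0)]})
    y = cohort.truth["single_band_class"].to_numpy()
    rep = cv_optimism(X, y, groups=cohort.patient_ids, kind="lr", seed=3)
    for m in rep.inner + rep.outer + [rep.global_inner]:
        assert m.bac == pytest.approx((m.sensitivity + m.specificity) / 2)
    assert 0.0 <= rep.corrected_auc <= 1.0
    assert 0.0 <= rep.corrected_bac <= 1.0


def test_roc_coordinates_span_unit_square(rng):
    scores = rng.random(50)
    labels = rng.integers(0, 2, size=50)
    df = roc_coordinates(scores, labels)
    assert df.iloc[0].tolist() == [0.0, 0.0]
    assert df.iloc[-1].tolist() == [1.0, 1.0]
    assert (df.diff().fillna(0) >= -1e-12).all().all()
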