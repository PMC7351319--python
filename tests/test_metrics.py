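import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from flimpipe.coregistration import FLIM_PARAMETERS
from flimpipe.metrics import (
    DiscriminationReport,
    average_precision,
    cohens_d,
    cohort_summary,
    fit_lda,
    lda_scores,
    patient_report,
    rank_sum_test,
    roc_auc,
)


# ---------------------------------------------------------------------------
# rank-sum test


def test_exact_p_value_worked_example():
    # enumeration oracle: 6 equally likely rank assignments, 2 as extreme
    assert abs(rank_sum_test([1.0, 2.0], [3.0, 4.0]) - 1.0 / 3.0) < 1e-12


def test_identical_samples_high_p():
    assert rank_sum_test([1.0, 2.0, 3.0] * 4, [1.0, 2.0, 3.0] * 4) >= 0.99


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])


def test_large_sample_shift_detected(rng):
    a = rng.normal(0, 1, 200)
    b = rng.normal(1.0, 1, 200)
    assert rank_sum_test(a, b) < 1e-6


# ---------------------------------------------------------------------------
# ROC-AUC


def test_auc_worked_example():
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75


def test_auc_perfect_and_ties():
    assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
    assert roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5


def test_auc_equals_u_statistic_exhaustive(rng):
    # pairwise-comparison oracle on tie-free samples up to n = 10
    for _ in range(50):
        n1, n0 = rng.integers(1, 6), rng.integers(1, 6)
        scores = rng.permutation(np.arange(n1 + n0, dtype=float) + rng.uniform(0, 0.5))
        labels = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
        pos, neg = scores[labels], scores[~labels]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert abs(roc_auc(scores, labels) - u / (n1 * n0)) < 1e-12


def test_auc_matches_sklearn(rng):
    for _ in range(20):
        scores = rng.normal(0, 1, 40)
        labels = rng.integers(0, 2, 40).astype(bool)
        if labels.all() or not labels.any():
            continue
        assert abs(roc_auc(scores, labels) - roc_auc_score(labels, scores)) < 1e-12


def test_auc_monotone_transform_invariant(rng):
    scores = rng.normal(0, 1, 60)
    labels = rng.integers(0, 2, 60).astype(bool)
    labels[0], labels[1] = True, False
    a1 = roc_auc(scores, labels)
    a2 = roc_auc(np.exp(3.0 * scores) + 7.0, labels)
    assert abs(a1 - a2) < 1e-12


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# average precision


def test_ap_worked_example():
    # step-sum oracle: 0.5*1 + 0.5*(2/3)
    assert abs(average_precision([0.9, 0.8, 0.7], [1, 0, 1]) - 5.0 / 6.0) < 1e-12


def test_ap_perfect_ranking():
    assert average_precision([3, 2, 1], [1, 1, 0]) == 1.0


def test_ap_single_positive_last():
    assert abs(average_precision([0.9, 0.8, 0.7], [0, 0, 1]) - 1.0 / 3.0) < 1e-12


def test_ap_matches_sklearn(rng):
    for _ in range(20):
        scores = rng.normal(0, 1, 50)
        labels = rng.integers(0, 2, 50).astype(bool)
        if not labels.any():
            continue
        assert abs(average_precision(scores, labels) - average_precision_score(labels, scores)) < 1e-10


def test_ap_random_scores_near_prevalence(rng):
    # Monte-Carlo: for random rankings E[AP] ~ prevalence
    prevalence = 0.3
    n = 500
    aps = []
    for _ in range(400):
        labels = rng.random(n) < prevalence
        if not labels.any():
            continue
        aps.append(average_precision(rng.normal(0, 1, n), labels))
    assert abs(np.mean(aps) - prevalence) < 0.02


def test_ap_no_positive_rejected():
    with pytest.raises(ValueError):
        average_precision([1.0, 2.0], [0, 0])


# ---------------------------------------------------------------------------
# Cohen's d


def test_cohens_d_identical_zero(rng):
    a = rng.normal(0, 1, 30)
    assert cohens_d(a, a.copy()) == 0.0


def test_cohens_d_unit_shift(rng):
    a = rng.normal(1.0, 1.0, 20000)
    b = rng.normal(0.0, 1.0, 20000)
    assert abs(abs(cohens_d(a, b)) - 1.0) < 0.05


def test_cohens_d_translation_invariant(rng):
    a = rng.normal(0, 1, 50)
    b = rng.normal(0.4, 1.2, 60)
    assert np.isclose(cohens_d(a, b), cohens_d(a + 13.0, b + 13.0))


def test_cohens_d_degenerate():
    assert np.isnan(cohens_d([1.0, 1.0, 1.0], [2.0, 2.0]))
    with pytest.raises(ValueError):
        cohens_d([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# LDA


def test_lda_concentrates_on_informative_feature(rng):
    n = 8000
    X = rng.normal(0, 1, (n, 6))
    y = np.r_[np.ones(n // 2, bool), np.zeros(n - n // 2, bool)]
    X[y, 3] += 2.0
    w = fit_lda(X, y)
    assert abs(w[3]) > 0.9
    others = np.delete(np.abs(w), 3)
    assert np.all(others < 0.05)


def test_lda_matches_analytic_direction(rng):
    # closed-form oracle: w proportional to Sigma^-1 (mu1 - mu0)
    cov = np.array([[1.0, 0.6], [0.6, 2.0]])
    delta = np.array([1.0, 0.5])
    n = 2000
    L = np.linalg.cholesky(cov)
    X0 = rng.normal(0, 1, (n, 2)) @ L.T
    X1 = rng.normal(0, 1, (n, 2)) @ L.T + delta
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n, bool), np.ones(n, bool)]
    w = fit_lda(X, y)
    w_true = np.linalg.solve(cov, delta)
    w_true = w_true / np.linalg.norm(w_true)
    angle = np.degrees(np.arccos(np.clip(abs(w @ w_true), -1, 1)))
    assert angle < 5.0


def test_lda_duplicated_features_ridge_path(rng):
    X = rng.normal(0, 1, (60, 3))
    X = np.column_stack([X, X[:, 0]])  # duplicate column
    y = np.r_[np.ones(30, bool), np.zeros(30, bool)]
    X[y, 1] += 1.0
    with pytest.warns(UserWarning, match="ridge"):
        w = fit_lda(X, y)
    assert np.all(np.isfinite(w))


def test_lda_sign_convention(rng):
    X = rng.normal(0, 1, (200, 2))
    y = np.r_[np.ones(100, bool), np.zeros(100, bool)]
    X[y, 0] += 1.5
    w = fit_lda(X, y)
    scores = X @ w
    assert scores[y].mean() > scores[~y].mean()


def test_lda_scores_contract(rng):
    X = rng.normal(0, 1, (50, 4))
    w = np.array([1.0, -0.5, 0.2, 0.0])
    s = lda_scores(X, w)
    assert s.min() == 0.0 and s.max() == 1.0
    proj = X @ w
    assert np.array_equal(np.argsort(s), np.argsort(proj))


def test_lda_scores_constant_projection():
    X = np.ones((10, 3))
    s = lda_scores(X, np.array([1.0, 1.0, 1.0]))
    assert np.all(s == 0.5)


def test_lda_feature_rescaling_invariance(rng):
    n = 500
    X = rng.normal(0, 1, (n, 4))
    y = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
    X[y, 0] += 1.0
    X[y, 2] += 0.5
    s1 = lda_scores(X, fit_lda(X, y))
    X2 = X.copy()
    X2[:, 1] = X2[:, 1] * 50.0 - 3.0  # affine rescale of one feature
    s2 = lda_scores(X2, fit_lda(X2, y))
    assert np.abs(s1 - s2).max() < 1e-6


# ---------------------------------------------------------------------------
# patient reports


def _toy_labeled(rng, n=60, contrast=2.0, with_cancer=True):
    half = n // 2
    rows = {
        "binary": ["cancer"] * half + ["healthy"] * (n - half) if with_cancer else ["healthy"] * n,
        "condition": ["cancer"] * half + ["healthy_epithelium"] * (n - half)
        if with_cancer
        else ["healthy_epithelium"] * n,
        "unlabeled": [False] * n,
        "heterogeneity_excluded": [False] * n,
        "snr_pass": [True] * n,
    }
    df = pd.DataFrame(rows)
    for i, p in enumerate(FLIM_PARAMETERS):
        shift = contrast if i == 0 else 0.0
        df[p] = rng.normal(4.0, 0.5, n)
        df.loc[df["binary"] == "cancer", p] += shift
        df[f"mad_pass_{p}"] = True
    df["mad_pass"] = True
    return df


def test_patient_report_contrast(rng):
    df = _toy_labeled(rng)
    report = patient_report(df, patient_id=1, context="in_vivo_pre")
    assert report.discriminable
    assert report.per_parameter["lifetime_ch1"]["p_value"] < 1e-3
    assert report.per_parameter["lifetime_ch1"]["auc"] > 0.9
    assert 0.0 <= report.lda_auc <= 1.0
    assert len(report.lda_weights) == 6


def test_patient_report_missing_class(rng):
    df = _toy_labeled(rng, with_cancer=False)
    report = patient_report(df, patient_id=9, context="in_vivo_pre")
    assert not report.discriminable
    assert report.per_parameter == {}


def test_report_serialization_round_trip(rng):
    report = patient_report(_toy_labeled(rng), patient_id=2, context="ex_vivo")
    clone = DiscriminationReport.from_json(report.to_json())
    assert clone.to_dict() == report.to_dict()


def test_cohort_summary_layout(rng):
    reports = [
        patient_report(_toy_labeled(rng), patient_id=i, context="in_vivo_pre") for i in (1, 2)
    ]
    summary = cohort_summary(reports)
    assert set(summary["parameter"]) == set(FLIM_PARAMETERS) | {"lda"}
    assert summary["mean_auc"].between(0, 1).all()
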