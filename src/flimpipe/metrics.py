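"""Per-patient, per-context discrimination statistics.

Implements the rank-sum test wrapper, rank-based ROC-AUC, step-function
average precision, pooled-SD Cohen's d, and the six-parameter Fisher LDA
variable with per-scan min-max scaling.  Cancer is the positive class
throughout; the LDA sign is fixed so cancer scores higher.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coregistration import FLIM_PARAMETERS

__all__ = [
    "rank_sum_test",
    "roc_auc",
    "average_precision",
    "cohens_d",
    "fit_lda",
    "lda_scores",
    "DiscriminationReport",
    "patient_report",
    "cohort_summary",
    "context_effect_sizes",
]


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when min(n1, n2) <= 8 and there are no ties;
    continuity-corrected normal approximation with midranks otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def roc_auc(scores, labels) -> float:
    """Probability a random positive outranks a random negative; ties 1/2.

    Computed from midranks (exactly U / (n1 n0)); raises on single-class
    input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def average_precision(scores, labels) -> float:
    """Step-interpolated average precision, positives ranked by descending
    score.  Tied scores are grouped at a single threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average_precision requires at least one positive")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order].astype(float)
    tp = np.cumsum(y)
    fp = np.cumsum(1.0 - y)
    # collapse tied thresholds: keep the last index of each distinct score
    distinct = np.r_[s[1:] != s[:-1], True]
    tp = tp[distinct]
    fp = fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    drecall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * drecall))


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean(a) - mean(b)) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d requires >= 2 values per sample")
    n1, n2 = a.size, b.size
    pooled = np.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        diff = a.mean() - b.mean()
        return 0.0 if diff == 0 else float("nan")
    return float((a.mean() - b.mean()) / pooled)


def fit_lda(features, labels, ridge: float = 1e-6):
    """One-dimensional Fisher discriminant direction via SVD.

    Solves Sw w = (mu_pos - mu_neg) through the SVD of the pooled
    within-class scatter; when Sw is numerically singular (e.g. duplicated
    features), a ridge of ``ridge * trace(Sw)`` is added and a warning is
    emitted.  The sign is fixed so the positive class scores higher; the
    returned vector has unit norm.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(bool)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("fit_lda requires both classes")
    mu_pos = X[y].mean(axis=0)
    mu_neg = X[~y].mean(axis=0)
    centered = X.copy()
    centered[y] -= mu_pos
    centered[~y] -= mu_neg
    sw = centered.T @ centered
    u, s, vt = np.linalg.svd(sw)
    rcond = s[0] * max(X.shape[1], 1) * np.finfo(float).eps if s.size else 0.0
    if s.size == 0 or s[-1] <= max(rcond, 1e-12 * s[0]):
        warnings.warn("singular within-class scatter; applying ridge", stacklevel=2)
        sw = sw + np.eye(sw.shape[0]) * ridge * max(np.trace(sw), 1e-30)
        u, s, vt = np.linalg.svd(sw)
    w = vt.T @ ((u.T @ (mu_pos - mu_neg)) / s)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate discriminant (identical class means)")
    w = w / norm
    if (mu_pos - mu_neg) @ w < 0:
        w = -w
    return w


def lda_scores(features, weights):
    """Project onto the discriminant and min-max scale to [0, 1] per scan.

    A constant projection returns all 0.5 (flagged by the caller via the
    degenerate range).
    """
    X = np.asarray(features, dtype=float)
    proj = X @ np.asarray(weights, dtype=float)
    lo, hi = proj.min(), proj.max()
    if hi == lo:
        return np.full(proj.shape, 0.5)
    return (proj - lo) / (hi - lo)


@dataclass
class DiscriminationReport:
    """Single-parameter and LDA discrimination results for one scan."""

    patient_id: int
    context: str
    n_healthy: int
    n_cancer: int
    discriminable: bool
    per_parameter: dict = field(default_factory=dict)  # name -> {p_value, auc, ap, n}
    lda_weights: list = field(default_factory=list)
    lda_auc: float = float("nan")
    lda_ap: float = float("nan")
    lda_p_value: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "context": self.context,
            "n_healthy": self.n_healthy,
            "n_cancer": self.n_cancer,
            "discriminable": self.discriminable,
            "per_parameter": self.per_parameter,
            "lda_weights": list(self.lda_weights),
            "lda_auc": self.lda_auc,
            "lda_ap": self.lda_ap,
            "lda_p_value": self.lda_p_value,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DiscriminationReport":
        return cls(**json.loads(text))

    def best_single_auc(self) -> float:
        return max(v["auc"] for v in self.per_parameter.values())

    def best_single_ap(self) -> float:
        return max(v["ap"] for v in self.per_parameter.values())

    def min_p_value(self) -> float:
        return min(v["p_value"] for v in self.per_parameter.values())


def patient_report(
    labeled: pd.DataFrame,
    patient_id: int = 0,
    context: str = "",
    positive: str = "cancer",
) -> DiscriminationReport:
    """Build the per-scan report from a filtered, labeled table.

    Univariate statistics use the per-parameter MAD masks; the LDA uses the
    rows passing every mask.  A scan missing one of the binary classes is
    marked non-discriminable (mirroring patients without intrapatient
    contrast) and carries counts only.
    """
    df = labeled
    base = (~df["unlabeled"]) & (~df["heterogeneity_excluded"]) & df["snr_pass"]
    binary = df["binary"].to_numpy()
    is_pos = (binary == positive) & base.to_numpy()
    is_neg = (binary != positive) & (binary != "") & base.to_numpy()
    n_cancer = int(is_pos.sum())
    n_healthy = int(is_neg.sum())
    report = DiscriminationReport(
        patient_id=patient_id,
        context=context,
        n_healthy=n_healthy,
        n_cancer=n_cancer,
        discriminable=n_cancer > 0 and n_healthy > 0,
    )
    if not report.discriminable:
        return report
    for p in FLIM_PARAMETERS:
        mask = df[f"mad_pass_{p}"].to_numpy() if f"mad_pass_{p}" in df else base.to_numpy()
        pos = df.loc[is_pos & mask, p].to_numpy(dtype=float)
        neg = df.loc[is_neg & mask, p].to_numpy(dtype=float)
        if pos.size == 0 or neg.size == 0:
            report.per_parameter[p] = {
                "p_value": float("nan"),
                "auc": float("nan"),
                "ap": float("nan"),
                "n": 0,
            }
            continue
        scores = np.concatenate([pos, neg])
        labels = np.r_[np.ones(pos.size, bool), np.zeros(neg.size, bool)]
        report.per_parameter[p] = {
            "p_value": rank_sum_test(pos, neg),
            "auc": roc_auc(scores, labels),
            "ap": average_precision(scores, labels),
            "n": int(pos.size + neg.size),
        }
    lda_mask = df["mad_pass"].to_numpy() if "mad_pass" in df else base.to_numpy()
    rows = (is_pos | is_neg) & lda_mask
    X = df.loc[rows, FLIM_PARAMETERS].to_numpy(dtype=float)
    y = (df.loc[rows, "binary"] == positive).to_numpy()
    if y.sum() > 0 and y.sum() < y.size:
        with warnings.catch_warnings():
            # the three intensity ratios sum to one, so the within-class
            # scatter is rank-deficient by construction; the ridge path is
            # expected here
            warnings.simplefilter("ignore", UserWarning)
            w = fit_lda(X, y)
        scores = lda_scores(X, w)
        report.lda_weights = [float(v) for v in w]
        report.lda_auc = roc_auc(scores, y)
        report.lda_ap = average_precision(scores, y)
        report.lda_p_value = rank_sum_test(scores[y], scores[~y])
    return report


def cohort_summary(reports) -> pd.DataFrame:
    """Per-context mean AUC/AP per parameter plus the LDA variable, over
    discriminable scans (layout of the patient-level comparison figures)."""
    rows = []
    for r in reports:
        if not r.discriminable:
            continue
        for p, v in r.per_parameter.items():
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "context": r.context,
                    "parameter": p,
                    "p_value": v["p_value"],
                    "auc": v["auc"],
                    "ap": v["ap"],
                }
            )
        rows.append(
            {
                "patient_id": r.patient_id,
                "context": r.context,
                "parameter": "lda",
                "p_value": r.lda_p_value,
                "auc": r.lda_auc,
                "ap": r.lda_ap,
            }
        )
    long = pd.DataFrame(rows)
    if long.empty:
        return long
    return (
        long.groupby(["context", "parameter"])[["auc", "ap"]]
        .mean()
        .reset_index()
        .rename(columns={"auc": "mean_auc", "ap": "mean_ap"})
    )


def context_effect_sizes(
    labeled_by_context: dict,
    condition: str = "healthy_epithelium",
    parameters=FLIM_PARAMETERS,
) -> pd.DataFrame:
    """Cohen's d of each parameter between pairs of imaging contexts, for
    one tissue condition pooled over patients."""
    contexts = list(labeled_by_context)
    rows = []
    for i, c1 in enumerate(contexts):
        for c2 in contexts[i + 1 :]:
            d1 = labeled_by_context[c1]
            d2 = labeled_by_context[c2]
            for p in parameters:
                a = d1.loc[(d1["condition"] == condition) & d1["analysis_ok"], p]
                b = d2.loc[(d2["condition"] == condition) & d2["analysis_ok"], p]
                if len(a) >= 2 and len(b) >= 2:
                    rows.append(
                        {
                            "context_a": c1,
                            "context_b": c2,
                            "parameter": p,
                            "effect_size": abs(cohens_d(a, b)),
                        }
                    )
    return pd.DataFrame(rows)
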