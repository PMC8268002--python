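"""ROC analysis, Youden operating points, contingency diagnostics,
bootstrap confidence intervals, and the DeLong test.

Binary radiologic signs (satellites, unclear interface, ...) are scored
from 2x2 contingency counts; their AUC is (sensitivity + specificity)/2,
the area under the single-operating-point ROC polygon.  Continuous model
scores get the Mann-Whitney AUC with half-credit for ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of a binary sign against STAS status."""

    tp: int  # sign-positive, STAS+
    fn: int  # sign-negative, STAS+
    fp: int  # sign-positive, STAS-
    tn: int  # sign-negative, STAS-

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class EvalReport:
    """Diagnostic metrics at an operating point, with optional CI."""

    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    threshold: float = float("nan")
    youden_j: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "auc", "sensitivity", "specificity", "accuracy", "ppv", "npv",
            "threshold", "youden_j", "ci_low", "ci_high", "n_boot",
        )}


#: Binary radiologic signs vs STAS status in the emulated 56/160 study
#: cohort (sign-positive counts among STAS+ and STAS- cases); the worked
#: inputs for the traditional-sign diagnostics.
STUDY_SIGN_COUNTS: dict[str, "ContingencyTable"] = {}


def _register_signs() -> None:
    for name, (pos, neg) in {
        "solid_nodule": (32, 63),
        "irregular_shape": (27, 108),
        "cystic_airspaces": (13, 65),
        "unclear_tumor_lung_interface": (38, 52),
        "satellites": (14, 6),
    }.items():
        STUDY_SIGN_COUNTS[name] = ContingencyTable(tp=pos, fn=56 - pos, fp=neg, tn=160 - neg)


def metrics_from_counts(t: ContingencyTable) -> EvalReport:
    """Diagnostics of a binary sign; undefined rates become NaN, never 0."""

    def _rate(num: int, den: int) -> float:
        if den == 0:
            warnings.warn("zero denominator; rate undefined")
            return float("nan")
        return num / den

    sens = _rate(t.tp, t.tp + t.fn)
    spec = _rate(t.tn, t.fp + t.tn)
    return EvalReport(
        auc=(sens + spec) / 2,
        sensitivity=sens,
        specificity=spec,
        accuracy=_rate(t.tp + t.tn, t.total),
        ppv=_rate(t.tp, t.tp + t.fp),
        npv=_rate(t.tn, t.tn + t.fn),
        youden_j=sens + spec - 1,
        threshold=0.5,
    )


def _check_scores(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def roc_curve_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(fpr, tpr, thresholds, AUC); AUC is the Mann-Whitney statistic."""
    scores, labels = _check_scores(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return fpr, tpr, thr, float(roc_auc_score(labels, scores))


def youden_threshold(scores, labels) -> tuple[float, EvalReport]:
    """Operating point maximizing J = sens + spec - 1.

    Ties break toward higher sensitivity, then toward the lower threshold.
    A case scores positive when its score is >= the threshold.
    """
    scores, labels = _check_scores(scores, labels)
    fpr, tpr, thr, auc = roc_curve_auc(scores, labels)
    j = tpr - fpr
    # np.lexsort picks the last max under ties; order candidates so that the
    # preferred one (higher sens, then lower threshold) wins
    order = np.lexsort((-thr, tpr, j))
    best = order[-1]
    cut = float(thr[best])
    pred = scores >= cut
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    rep = metrics_from_counts(ContingencyTable(tp, fn, fp, tn))
    rep.auc = auc  # full-curve AUC, not the single-point polygon
    rep.threshold = cut
    return cut, rep


def bootstrap_ci(
    scores, labels, n_boot: int = 1000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Percentile bootstrap CI of the AUC with stratified case resampling."""
    scores, labels = _check_scores(scores, labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        aucs[b] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    # heaviside kernel with half credit for ties
    cmp = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(cmp.mean())


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for two correlated AUCs on the same cases."""
    from scipy import stats

    scores_a, labels = _check_scores(scores_a, labels)
    scores_b = np.asarray(scores_b, float)
    if scores_b.shape != labels.shape:
        raise ValueError("paired score vectors must have equal length")
    v10a, v01a, auc_a = _placements(scores_a, labels)
    v10b, v01b, auc_b = _placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


_register_signs()
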