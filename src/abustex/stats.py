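"""Evaluation statistics: per-feature group tests, ROC/AUC with DeLong
confidence intervals, comparison of correlated ROC curves, confusion
metrics, two-reader ICC and the feature correlation matrix.

AUC is computed by the Mann-Whitney equivalence (ties weighted 1/2) via
placement values, which also yield the DeLong variance.  Confidence
intervals for a single AUC are formed on the logit scale so they stay
inside [0, 1].  Inter-reader agreement uses the two-way random-effects,
absolute-agreement, single-measurement ICC — ICC(2,1) — interpreted on
the Landis-Koch scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError, ParameterError

__all__ = [
    "ROCResult",
    "DeLongResult",
    "ICCResult",
    "ConfusionReport",
    "anova_per_feature",
    "ttest_per_feature",
    "roc_with_ci",
    "delong_compare",
    "icc_two_reader",
    "confusion_metrics",
    "feature_correlation_matrix",
    "landis_koch_category",
]

BONFERRONI_GATE = 1e-4  # fixed significance gate for the 4-group ANOVA screen


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float
    p_value: float


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    category: str


@dataclass(frozen=True)
class ConfusionReport:
    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive) and V01 (per negative) and the AUC.

    V10_i is the fraction of negatives scored below positive i (ties
    count 1/2); the AUC is the mean placement.  Computed with midranks.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ParameterError("both classes must be present")
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - sps.rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - sps.rankdata(neg)) / m
    return v10, v01, float(v10.mean())


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_with_ci(scores, labels) -> ROCResult:
    """ROC curve with Mann-Whitney AUC and a DeLong 95% CI (logit scale)."""
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    v10, v01, auc = _placements(scores, labels)
    var = _auc_variance(v10, v01)
    se = np.sqrt(var)
    eps = 1e-12
    if se == 0.0 or auc <= eps or auc >= 1 - eps:
        # no sampling spread on the logit scale; degenerate pointwise CI
        lo = hi = auc
        if se > 0:  # AUC exactly 0/1 but finite variance: clamp via logit at the boundary
            a = min(max(auc, 1e-6), 1 - 1e-6)
            logit = np.log(a / (1 - a))
            half = 1.959963984540054 * se / (a * (1 - a))
            lo = 1 / (1 + np.exp(-(logit - half)))
            hi = 1 / (1 + np.exp(-(logit + half)))
    else:
        logit = np.log(auc / (1 - auc))
        half = 1.959963984540054 * se / (auc * (1 - auc))
        lo = 1 / (1 + np.exp(-(logit - half)))
        hi = 1 / (1 + np.exp(-(logit + half)))
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        one_minus_specificity=fpr,
        auc=auc,
        ci95=(float(lo), float(hi)),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
    )


def delong_compare(
    scores_a,
    scores_b,
    labels,
    paired: bool = True,
    labels_b=None,
) -> DeLongResult:
    """DeLong test comparing two AUCs.

    In paired mode both score vectors refer to the same samples/labels
    and the covariance of placement values is used; in unpaired mode the
    variances simply add (``labels_b`` gives the second sample's labels).
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels)
    if paired:
        if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
            raise ParameterError("paired mode requires equally shaped score/label vectors")
        va10, va01, auc_a = _placements(scores_a, labels)
        vb10, vb01, auc_b = _placements(scores_b, labels)
        m, n = va10.size, va01.size
        if m > 1:
            s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
        else:
            s10 = np.zeros((2, 2))
        if n > 1:
            s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
        else:
            s01 = np.zeros((2, 2))
        cov = s10 / m + s01 / n
        var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    else:
        if labels_b is None:
            raise ParameterError("unpaired mode requires labels_b")
        va10, va01, auc_a = _placements(scores_a, labels)
        vb10, vb01, auc_b = _placements(scores_b, np.asarray(labels_b))
        var = _auc_variance(va10, va01) + _auc_variance(vb10, vb01)
    delta = float(auc_a - auc_b)
    if var <= 1e-15:
        if abs(delta) <= 1e-12:
            return DeLongResult(auc_a, auc_b, 0.0, 0.0, 0.0, 1.0)
        raise DegenerateVarianceError(
            f"zero DeLong variance with nonzero AUC difference {delta:g}"
        )
    z = delta / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return DeLongResult(float(auc_a), float(auc_b), delta, var, float(z), p)


def landis_koch_category(icc: float) -> str:
    """Verbal agreement category for an agreement coefficient."""
    if icc <= 0.40:
        return "poor/fair"
    if icc <= 0.60:
        return "moderate"
    if icc <= 0.80:
        return "substantial"
    return "almost perfect"


def icc_two_reader(values_reader1, values_reader2) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    The 95% CI follows the McGraw-Wong F-based construction with a
    Satterthwaite degrees-of-freedom approximation.
    """
    x1 = np.asarray(values_reader1, dtype=np.float64)
    x2 = np.asarray(values_reader2, dtype=np.float64)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ParameterError("readers must supply equally long 1-D value vectors")
    n = x1.size
    if n < 3:
        raise ParameterError("need at least 3 paired measurements")
    data = np.column_stack([x1, x2])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise DegenerateVarianceError("zero total variance: ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sst = np.sum((data - grand) ** 2)
    sse = sst - k * np.sum((row_means - grand) ** 2) - n * np.sum((col_means - grand) ** 2)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom > 0 else 1.0

    if mse <= 1e-30 and msc <= 1e-30:
        ci = (icc, icc)
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isinf(a):
            ci = (icc, icc)
        else:
            b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
            v = num / den if den > 0 else (n - 1.0) * (k - 1.0)
            f1 = sps.f.ppf(0.975, n - 1.0, v)
            f2 = sps.f.ppf(0.975, v, n - 1.0)
            lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
            ci = (float(lo), float(hi))
    return ICCResult(icc=icc, ci95=ci, category=landis_koch_category(icc))


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if table[c].dtype.kind == "f"]


def anova_per_feature(table: pd.DataFrame, labels, feature_names=None) -> pd.DataFrame:
    """One-way ANOVA per feature across the (four) tissue classes.

    Significance is a fixed p < 1e-4 gate (the Bonferroni-corrected
    screen used for the 47-feature comparison).  When both between- and
    within-group variance vanish the test is uninformative and p is set
    to 1.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ParameterError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 samples")
    cols = list(feature_names) if feature_names is not None else _feature_columns(table)
    rows = []
    for c in cols:
        x = table[c].to_numpy(dtype=np.float64)
        parts = [x[labels == g] for g in groups]
        if all(np.ptp(p) == 0 for p in parts) and np.ptp(x) == 0:
            f_stat, p = 0.0, 1.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                f_stat, p = sps.f_oneway(*parts)
            if np.isnan(f_stat):
                f_stat, p = 0.0, 1.0
            elif np.isinf(f_stat):
                p = 0.0
        rows.append({"feature": c, "F": float(f_stat), "p": float(p),
                     "significant": bool(p < BONFERRONI_GATE)})
    return pd.DataFrame(rows)


def ttest_per_feature(table: pd.DataFrame, labels, feature_names=None) -> pd.DataFrame:
    """Two-sided unpaired t test per feature between two groups."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ParameterError("exactly 2 groups required")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 samples")
    cols = list(feature_names) if feature_names is not None else _feature_columns(table)
    rows = []
    for c in cols:
        x = table[c].to_numpy(dtype=np.float64)
        a, b = x[labels == groups[0]], x[labels == groups[1]]
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = sps.ttest_ind(a, b)
        if np.isnan(t):  # zero pooled variance
            t, p = 0.0, 1.0
        rows.append({"feature": c, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def confusion_metrics(predicted, actual, positive=1) -> ConfusionReport:
    """2x2 confusion counts and accuracy/sensitivity/specificity."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.size == 0:
        raise ParameterError("empty input")
    if predicted.shape != actual.shape:
        raise ParameterError("predicted and actual must have equal length")
    p = predicted == positive
    a = actual == positive
    tp = int((p & a).sum())
    fn = int((~p & a).sum())
    fp = int((p & ~a).sum())
    tn = int((~p & ~a).sum())
    n_pos, n_neg = tp + fn, fp + tn
    return ConfusionReport(
        tp=tp, fn=fn, fp=fp, tn=tn,
        accuracy=(tp + tn) / (n_pos + n_neg),
        sensitivity=tp / n_pos if n_pos else 0.0,
        specificity=tn / n_neg if n_neg else 0.0,
    )


def feature_correlation_matrix(table: pd.DataFrame, feature_names=None) -> pd.DataFrame:
    """Pearson correlation matrix of the feature columns.

    Constant columns have undefined correlations; their off-diagonal
    entries are set to 0 (diagonal kept at 1) and flagged via the
    returned frame's ``attrs['constant_columns']``.
    """
    cols = list(feature_names) if feature_names is not None else _feature_columns(table)
    if len(table) < 3:
        raise ParameterError("need at least 3 rows")
    X = table[cols].to_numpy(dtype=np.float64)
    sd = X.std(axis=0)
    constant = [c for c, s in zip(cols, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    out = pd.DataFrame(corr, index=cols, columns=cols)
    out.attrs["constant_columns"] = constant
    return out
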