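"""Diagnostic-performance statistics for perfusion thresholds.

ROC analysis with trapezoidal AUC and maximal-Youden operating points,
DeLong's nonparametric comparison of correlated AUCs, Bland–Altman
agreement, Cohen's kappa for observer agreement, Welch's two-sample
t-test, and sensitivity/specificity/PPV/NPV with Wilson-score
confidence intervals.

Perfusion scores indicate disease when *low* (reduced MBF or MPR), so
every ROC entry point takes a ``low_is_positive`` flag; internally the
scores are negated, keeping the ROC machinery direction-agnostic while
reporting thresholds on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa
from statsmodels.stats.proportion import proportion_confint


class DiagnosticsError(ValueError):
    """Raised for inputs the statistic is undefined on."""


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Empirical ROC curve with trapezoidal AUC and Youden operating point.

    ``thresholds`` are on the original score scale, one per candidate
    cut (midpoints between consecutive distinct scores plus the two
    infinite sentinels); ``sensitivity[i]``/``specificity[i]`` are the
    operating characteristics of calling disease at ``thresholds[i]``
    (score ≤ threshold when ``low_is_positive``, ≥ otherwise).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]
    low_is_positive: bool
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float

    @property
    def youden_j(self) -> float:
        return self.youden_sensitivity + self.youden_specificity - 1.0


def _placement_values(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values via midranks (ties counted one half)."""
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    r = stats.rankdata(combined)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r[:m] - r_pos) / n          # P(score_pos > score_neg) per positive
    v01 = 1.0 - (r[m:] - r_neg) / m    # per negative
    return v10, v01


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    low_is_positive: bool = True,
) -> ROCResult:
    """Empirical ROC curve, trapezoidal AUC and maximal-Youden threshold.

    The trapezoidal AUC over midpoint thresholds equals the
    Mann–Whitney pair statistic with ties counted one half.  The AUC
    standard error follows DeLong's placement-value estimator, with a
    Wald 95 % interval clipped to [0, 1].  The Youden threshold
    maximises J = sensitivity + specificity − 1; ties resolve toward
    higher sensitivity, then the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise DiagnosticsError("scores and labels must have equal length")
    positive = labels.astype(bool)
    m = int(positive.sum())
    n = int(scores.size - m)
    if m == 0 or n == 0:
        raise DiagnosticsError("need at least one positive and one negative case")

    oriented = -scores if low_is_positive else scores

    # Candidate cuts: midpoints between consecutive distinct oriented
    # scores, plus sentinels below and above everything.
    distinct = np.unique(oriented)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cuts = np.concatenate([[-np.inf], mids, [np.inf]])
    pos_sorted = np.sort(oriented[positive])
    neg_sorted = np.sort(oriented[~positive])
    # Predict positive when oriented score >= cut.
    sens = 1.0 - np.searchsorted(pos_sorted, cuts, side="left") / m
    spec = np.searchsorted(neg_sorted, cuts, side="left") / n

    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    v10, v01 = _placement_values(oriented[positive], oriented[~positive])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))

    j = sens + spec - 1.0
    # Tie-break: maximal J, then higher sensitivity, then lower
    # threshold on the original scale.
    thr_orig = -cuts if low_is_positive else cuts
    order = np.lexsort((thr_orig, -sens, -j))
    best = order[0]

    return ROCResult(
        thresholds=thr_orig,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=se,
        auc_ci=ci,
        low_is_positive=low_is_positive,
        youden_threshold=float(thr_orig[best]),
        youden_sensitivity=float(sens[best]),
        youden_specificity=float(spec[best]),
    )


def youden_threshold(roc: ROCResult) -> tuple[float, float, float]:
    """The maximal-Youden operating point as (threshold, sens, spec)."""
    return roc.youden_threshold, roc.youden_sensitivity, roc.youden_specificity


# ---------------------------------------------------------------------------
# DeLong comparison of correlated AUCs
# ---------------------------------------------------------------------------

@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    diff: float
    diff_se: float
    diff_ci: tuple[float, float]
    p_value: float
    var_a: float
    var_b: float


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    low_is_positive: bool = True,
) -> DeLongResult:
    """DeLong's test for two correlated ROC curves on paired scores.

    Placement-value covariances estimate the variance of the AUC
    difference; the two-sided p comes from the normal approximation.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (a.shape == b.shape == labels.shape):
        raise DiagnosticsError("paired scores and labels must have equal length")
    positive = labels.astype(bool)
    m = int(positive.sum())
    n = int(labels.size - m)
    if m == 0 or n == 0:
        raise DiagnosticsError("need at least one positive and one negative case")
    if low_is_positive:
        a, b = -a, -b

    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for i, s in enumerate((a, b)):
        v10[i], v01[i] = _placement_values(s[positive], s[~positive])
    aucs = v10.mean(axis=1)
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = max(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1], 0.0)
    diff = float(aucs[0] - aucs[1])
    se = float(np.sqrt(var_diff))
    if se == 0.0:
        z_stat = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        z_stat = diff / se
    p = float(2 * stats.norm.sf(abs(z_stat))) if np.isfinite(z_stat) else 0.0
    zc = stats.norm.ppf(0.975)
    return DeLongResult(
        auc_a=float(aucs[0]), auc_b=float(aucs[1]), diff=diff, diff_se=se,
        diff_ci=(diff - zc * se, diff + zc * se), p_value=min(p, 1.0),
        var_a=float(cov[0, 0]), var_b=float(cov[1, 1]),
    )


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(values_a: Sequence[float], values_b: Sequence[float]) -> BlandAltmanResult:
    """Bland–Altman agreement: bias = mean(a − b), limits ±1.96 SD."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise DiagnosticsError("paired value arrays must have equal length")
    if a.size < 2:
        raise DiagnosticsError("Bland-Altman requires at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd, loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd, n=a.size)


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci: tuple[float, float]
    p_observed: float
    p_expected: float


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> KappaResult:
    """Cohen's kappa for two raters, with the asymptotic 95 % interval."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise DiagnosticsError("rating sequences must have equal length")
    if a.size == 0:
        raise DiagnosticsError("no ratings supplied")
    cats = np.unique(np.concatenate([a, b]))
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((cats.size, cats.size))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    n = table.sum()
    p_o = float(np.trace(table) / n)
    p_e = float(np.sum(table.sum(axis=0) * table.sum(axis=1)) / n**2)
    if p_e >= 1.0 - 1e-12:
        raise DiagnosticsError("kappa undefined: both raters constant and equal")
    res = _sm_cohens_kappa(table, return_results=True)
    return KappaResult(kappa=float(res.kappa), se=float(res.std_kappa),
                       ci=(float(res.kappa_low), float(res.kappa_upp)),
                       p_observed=p_o, p_expected=p_e)


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns (t, dof, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DiagnosticsError("each group needs at least two observations")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Diagnostic metrics with Wilson intervals
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]


def diagnostic_metrics(tp: int, fp: int, tn: int, fn: int) -> DiagnosticMetrics:
    """Sens/spec/PPV/NPV from a 2×2 table, Wilson-score 95 % intervals."""
    for c, name in ((tp, "tp"), (fp, "fp"), (tn, "tn"), (fn, "fn")):
        if c < 0:
            raise DiagnosticsError(f"count {name} must be non-negative")

    def one(num: int, den: int, metric: str) -> tuple[float, tuple[float, float]]:
        if den == 0:
            raise DiagnosticsError(f"zero denominator for {metric}")
        lo, hi = proportion_confint(num, den, alpha=0.05, method="wilson")
        return num / den, (float(lo), float(hi))

    sens, sens_ci = one(tp, tp + fn, "sensitivity")
    spec, spec_ci = one(tn, tn + fp, "specificity")
    ppv, ppv_ci = one(tp, tp + fp, "PPV")
    npv, npv_ci = one(tn, tn + fn, "NPV")
    return DiagnosticMetrics(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
                             sensitivity_ci=sens_ci, specificity_ci=spec_ci,
                             ppv_ci=ppv_ci, npv_ci=npv_ci)
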