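"""Biomarker statistics: group comparison, logistic combination, ROC, DeLong.

This is the study's full statistical pipeline: per-marker normality-gated
group tests (t-test vs Mann-Whitney), chi-square for categorical tables,
binary logistic regression to combine significant markers, empirical ROC
curves with Youden-maximal cutoffs, and the DeLong test for comparing
correlated AUCs, plus a binormal analytic AUC used as an internal
consistency check between reported group distributions and reported AUCs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import DegenerateDataError, DomainError

__all__ = [
    "ComparisonResult",
    "RocResult",
    "LogisticModel",
    "select_and_compare",
    "chi_square_categorical",
    "fit_logistic",
    "roc_analysis",
    "delong_test",
    "delong_auc_variance",
    "binormal_auc",
    "operating_point",
]


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    marker: str
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float


def select_and_compare(values_neg, values_pos, marker: str = "",
                       normality_alpha: float = 0.05) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Shapiro-Wilk is run per group at ``normality_alpha``; if neither group
    rejects, an unpaired two-sided Student t-test is used, otherwise a
    two-sided Mann-Whitney U test.
    """
    a = np.asarray(values_neg, float)
    b = np.asarray(values_pos, float)
    if a.size < 3 or b.size < 3:
        raise DomainError("each group needs at least 3 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise DegenerateDataError("both groups are constant")

    def normal(x):
        if np.ptp(x) == 0:
            return False
        return sps.shapiro(x).pvalue >= normality_alpha

    if normal(a) and normal(b):
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        test = "t_test"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    return ComparisonResult(
        marker=marker, test_used=test, statistic=float(stat),
        p_value=float(p), mean_neg=float(a.mean()), sd_neg=float(a.std(ddof=1)),
        mean_pos=float(b.mean()), sd_pos=float(b.std(ddof=1)),
    )


def chi_square_categorical(table) -> tuple:
    """Pearson chi-square on a 2x2 (or rxc) count table.

    Yates continuity correction is applied when any expected count is < 5.
    Returns (statistic, p_value, correction_applied).
    """
    t = np.asarray(table, dtype=float)
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise DomainError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateDataError("table has a zero margin")
    expected = sps.contingency.expected_freq(t)
    correction = bool(expected.min() < 5)
    stat, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return float(stat), float(p), correction


# ---------------------------------------------------------------------------
# logistic combination
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    intercept: float
    coefficients: np.ndarray
    predictor_names: List[str]
    probabilities: np.ndarray
    converged: bool
    separation: bool
    score_norm: float  # max-norm of the log-likelihood gradient at the fit

    def predict(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        eta = self.intercept + x @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(x, y, names: Optional[Sequence[str]] = None) -> LogisticModel:
    """Unpenalized maximum-likelihood binary logistic regression.

    Newton/IRLS via statsmodels; complete separation is caught and flagged
    rather than raised, with the last iterate's (diverging) coefficients
    returned for inspection.
    """
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 1 and x.shape[1] > 1 and np.asarray(y).size == x.shape[1]:
        x = x.T
    y = np.asarray(y, float)
    classes = np.unique(y)
    if classes.size != 2:
        raise DomainError("labels must contain exactly two classes")
    y01 = (y == classes.max()).astype(float)
    if np.any(np.ptp(x, axis=0) == 0):
        raise DomainError("constant predictor column")
    names = list(names) if names is not None else [
        f"x{j}" for j in range(x.shape[1])
    ]

    design = sm.add_constant(x, has_constant="add")
    model = sm.Logit(y01, design)
    separation = False
    with warnings.catch_warnings():
        # separation produces benign overflow/convergence warnings; the
        # outcome is reported through the separation/converged flags instead
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
            params = res.params
            converged = bool(res.mle_retvals.get("converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            res = model.fit_regularized(alpha=1e-8, disp=0, maxiter=200)
            params = res.params
            converged = False
        prob = model.predict(params)
    if not separation and (prob.min() < 1e-10 or prob.max() > 1 - 1e-10):
        separation = True
        converged = False
    score = model.score(params) if not separation else np.full(params.size, np.inf)
    return LogisticModel(
        intercept=float(params[0]),
        coefficients=np.asarray(params[1:], float),
        predictor_names=names,
        probabilities=np.clip(prob, 1e-300, 1 - 1e-16),
        converged=converged,
        separation=separation,
        score_norm=float(np.max(np.abs(score))),
    )


# ---------------------------------------------------------------------------
# ROC / Youden / DeLong
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    auc_variance: float
    youden_cutoff: float
    youden_index: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    accuracy_at_cutoff: float
    n_pos: int
    n_neg: int


def operating_point(sens: float, spec: float, n_pos: int, n_neg: int):
    """Youden index and prevalence-weighted accuracy for an operating point.

    youden = sens + spec − 1; accuracy = (sens·n_pos + spec·n_neg)/(n_pos+n_neg).
    """
    youden = sens + spec - 1.0
    accuracy = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    return youden, accuracy


def _midrank_auc(scores: np.ndarray, labels01: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic, ties counted 1/2."""
    n_pos = int(labels01.sum())
    n_neg = labels01.size - n_pos
    ranks = sps.rankdata(scores)
    u = ranks[labels01 == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_analysis(scores, labels, positive_label=None) -> RocResult:
    """Empirical ROC with Youden-maximal cutoff and DeLong-variance CI.

    The decision rule is "positive if score >= threshold" over the unique
    observed scores; ties contribute 1/2 to the AUC (normalized U statistic).
    Youden ties are broken toward the higher cutoff, i.e. higher specificity.
    The 95% CI is a normal approximation with the DeLong variance, truncated
    to [0, 1].
    """
    s = np.asarray(scores, float)
    lab = np.asarray(labels)
    if positive_label is None:
        classes = np.unique(lab)
        if classes.size != 2:
            raise DomainError("labels must contain exactly two classes")
        positive_label = classes.max()
    y = (lab == positive_label).astype(int)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DomainError("both classes must be present")

    auc = _midrank_auc(s, y)
    var = delong_auc_variance(s, y)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci_low = float(np.clip(auc - half, 0.0, 1.0))
    ci_high = float(np.clip(auc + half, 0.0, 1.0))

    thresholds = np.unique(s)  # ascending; rule: score >= t -> positive
    sens = np.array([(s[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(s[y == 0] < t).mean() for t in thresholds])
    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())[-1]  # ties -> higher cutoff
    y_best, acc_best = operating_point(sens[best], spec[best], n_pos, n_neg)

    return RocResult(
        thresholds=thresholds, sensitivities=sens, specificities=spec,
        auc=auc, auc_ci_low=ci_low, auc_ci_high=ci_high, auc_variance=float(var),
        youden_cutoff=float(thresholds[best]), youden_index=float(y_best),
        sens_at_cutoff=float(sens[best]), spec_at_cutoff=float(spec[best]),
        accuracy_at_cutoff=float(acc_best), n_pos=n_pos, n_neg=n_neg,
    )


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    # midrank-based placement values
    v10 = np.empty(m)
    v01 = np.empty(n)
    order = np.argsort(neg, kind="mergesort")
    neg_sorted = neg[order]
    left = np.searchsorted(neg_sorted, pos, side="left")
    right = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (left + 0.5 * (right - left)) / n
    order = np.argsort(pos, kind="mergesort")
    pos_sorted = pos[order]
    left = np.searchsorted(pos_sorted, neg, side="left")
    right = np.searchsorted(pos_sorted, neg, side="right")
    v01 = 1.0 - (left + 0.5 * (right - left)) / m
    return v10, v01


def delong_auc_variance(scores, labels01) -> float:
    """DeLong variance of a single empirical AUC."""
    s = np.asarray(scores, float)
    y = np.asarray(labels01).astype(int)
    v10, v01 = _delong_components(s, y)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    auc_difference: float
    variance: float
    z: float
    p_value: float
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels, positive_label=None) -> DeLongResult:
    """DeLong comparison of two correlated AUCs measured on the same subjects.

    Two-sided z-test on the AUC difference with the structural-component
    covariance. A zero-variance difference (e.g. identical scores) is flagged
    degenerate with p = 1.
    """
    sa = np.asarray(scores_a, float)
    sb = np.asarray(scores_b, float)
    lab = np.asarray(labels)
    if sa.shape != sb.shape or sa.shape != lab.shape:
        raise DomainError("scores_a, scores_b and labels must be aligned")
    if positive_label is None:
        classes = np.unique(lab)
        if classes.size != 2:
            raise DomainError("labels must contain exactly two classes")
        positive_label = classes.max()
    y = (lab == positive_label).astype(int)
    if y.sum() in (0, y.size):
        raise DomainError("both classes must be present")

    auc_a = _midrank_auc(sa, y)
    auc_b = _midrank_auc(sb, y)
    va10, va01 = _delong_components(sa, y)
    vb10, vb01 = _delong_components(sb, y)
    m, n = va10.size, va01.size
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return DeLongResult(auc_a=auc_a, auc_b=auc_b, auc_difference=diff,
                            variance=0.0, z=0.0,
                            p_value=1.0 if diff == 0 else 0.0, degenerate=True)
    z = diff / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, auc_difference=float(diff),
                        variance=float(var_diff), z=float(z), p_value=float(p))


def binormal_auc(mu_neg: float, sd_neg: float, mu_pos: float, sd_pos: float) -> float:
    """Analytic AUC of two normal score distributions.

    Φ(|μ_pos − μ_neg| / sqrt(sd_pos² + sd_neg²)) — the probability that a
    random positive exceeds a random negative (folded so that AUC >= 0.5).
    """
    if sd_neg < 0 or sd_pos < 0 or (sd_neg == 0 and sd_pos == 0 and mu_neg == mu_pos):
        raise DomainError("need non-negative SDs, not both zero at equal means")
    denom = np.hypot(sd_neg, sd_pos)
    if denom == 0:
        return 1.0
    return float(sps.norm.cdf(abs(mu_pos - mu_neg) / denom))
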