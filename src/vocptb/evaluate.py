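"""Diagnostic-test statistics from cross-validated probabilities.

Computes the standard test-accuracy panel from pooled out-of-fold
probabilities: ROC curve, AUC (as the Mann–Whitney concordance
probability) with a DeLong 95% CI, an operating threshold (Youden's J
by default), sensitivity/specificity with Clopper–Pearson exact CIs,
PPV, NPV, the confusion counts, and a two-sided Mann–Whitney p-value
comparing the probability distributions of the two outcome groups.

AUC is defined as (concordant pairs + ½ tied pairs) / (n_pos × n_neg);
the ROC trapezoid equals it identically, which the tests assert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .modelling import CVResult

__all__ = [
    "PerformanceReport",
    "roc_curve",
    "auc",
    "auc_ci_bootstrap",
    "choose_threshold",
    "confusion_stats",
    "group_pvalue",
    "evaluate_probabilities",
    "evaluate_cv",
]


@dataclass
class PerformanceReport:
    """The test-accuracy panel for one analysis × classifier block."""

    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    npv: float
    group_p: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["auc_ci"] = list(self.auc_ci)
        d["sensitivity_ci"] = list(self.sensitivity_ci)
        d["specificity_ci"] = list(self.specificity_ci)
        return d


def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty input")
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("both outcome classes must be present")
    return labels, labels == 1


def roc_curve(probabilities, labels) -> list[tuple[float, float]]:
    """(FPR, TPR) points, one per distinct threshold, from (0,0) to (1,1)."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels, _ = _check_two_class(labels)
    fpr, tpr, _ = _sk_roc_curve(labels, probabilities, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong standard error of the AUC via placement values."""
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def auc(probabilities, labels) -> tuple[float, tuple[float, float]]:
    """Concordance-probability AUC with a DeLong 95% CI, clipped to [0, 1]."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels, is_pos = _check_two_class(labels)
    pos, neg = probabilities[is_pos], probabilities[~is_pos]
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    a = float(psi.mean())
    se = _delong_se(pos, neg)
    lo, hi = a - 1.959963984540054 * se, a + 1.959963984540054 * se
    return a, (max(0.0, lo), min(1.0, hi))


def auc_ci_bootstrap(
    probabilities, labels, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile-bootstrap 95% CI, for cross-checking DeLong."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels, is_pos = _check_two_class(labels)
    pos, neg = probabilities[is_pos], probabilities[~is_pos]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=pos.size, replace=True)
        n = rng.choice(neg, size=neg.size, replace=True)
        psi = (p[:, None] > n[None, :]) + 0.5 * (p[:, None] == n[None, :])
        aucs[b] = psi.mean()
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def choose_threshold(probabilities, labels) -> float:
    """Operating threshold maximising Youden's J = sens + spec − 1.

    Candidates are the observed probabilities (prediction positive iff
    probability ≥ threshold); ties in J are resolved toward higher
    specificity, i.e. the larger threshold.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels, is_pos = _check_two_class(labels)
    candidates = np.unique(probabilities)[::-1]  # descending: higher spec first
    n_pos, n_neg = is_pos.sum(), (~is_pos).sum()
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = probabilities >= t
        j = (pred & is_pos).sum() / n_pos + (~pred & ~is_pos).sum() / n_neg - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = t, j
    return float(best_t)


def _rate_ci(count: int, nobs: int) -> tuple[float, tuple[float, float]]:
    if nobs == 0:
        warnings.warn("rate undefined (zero denominator)", RuntimeWarning, stacklevel=3)
        return float("nan"), (float("nan"), float("nan"))
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="beta")
    return count / nobs, (float(lo), float(hi))


def confusion_stats(probabilities, labels, threshold: float) -> dict:
    """Confusion counts and rate panel at a fixed threshold.

    Prediction is positive iff probability ≥ threshold.  Sensitivity and
    specificity carry Clopper–Pearson exact 95% CIs; rates with a zero
    denominator are reported as NaN with a warning rather than raising.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels, is_pos = _check_two_class(labels)
    pred = probabilities >= threshold
    tp = int((pred & is_pos).sum())
    fp = int((pred & ~is_pos).sum())
    tn = int((~pred & ~is_pos).sum())
    fn = int((~pred & is_pos).sum())
    sens, sens_ci = _rate_ci(tp, tp + fn)
    spec, spec_ci = _rate_ci(tn, tn + fp)
    ppv, _ = _rate_ci(tp, tp + fp)
    npv, _ = _rate_ci(tn, tn + fn)
    return {
        "threshold": float(threshold),
        "sensitivity": sens,
        "sensitivity_ci": sens_ci,
        "specificity": spec,
        "specificity_ci": spec_ci,
        "ppv": ppv,
        "npv": npv,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def group_pvalue(probabilities, labels) -> float:
    """Two-sided Mann–Whitney p comparing probabilities across outcomes."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels, is_pos = _check_two_class(labels)
    pos, neg = probabilities[is_pos], probabilities[~is_pos]
    if np.all(probabilities == probabilities[0]):
        return 1.0  # all tied: no evidence either way
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    return 1.0 if not np.isfinite(p) else min(p, 1.0)


def evaluate_probabilities(
    probabilities, labels, threshold: float | str = "youden"
) -> PerformanceReport:
    """Full panel from pooled probabilities.

    ``threshold`` is either the string ``"youden"`` (maximise J) or a
    fixed numeric cutoff such as 0.5.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    t = choose_threshold(probabilities, labels) if threshold == "youden" else float(threshold)
    a, ci = auc(probabilities, labels)
    c = confusion_stats(probabilities, labels, t)
    return PerformanceReport(
        auc=a,
        auc_ci=ci,
        threshold=t,
        sensitivity=c["sensitivity"],
        sensitivity_ci=tuple(c["sensitivity_ci"]),
        specificity=c["specificity"],
        specificity_ci=tuple(c["specificity_ci"]),
        ppv=c["ppv"],
        npv=c["npv"],
        group_p=group_pvalue(probabilities, labels),
        tp=c["tp"],
        fp=c["fp"],
        tn=c["tn"],
        fn=c["fn"],
    )


def evaluate_cv(result: CVResult, threshold: float | str = "youden") -> PerformanceReport:
    """Panel for a cross-validation result's out-of-fold probabilities."""
    return evaluate_probabilities(result.probabilities, result.labels, threshold)
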