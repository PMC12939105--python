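"""Discrimination, thresholded metrics, calibration and score-distribution
statistics for the rad-PDL1 score."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


def _check_scores(scores, labels):
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    return s, y


def roc_auc(scores, labels) -> float:
    """AUC = P(score_1 > score_0) with ties counted 1/2.

    Identical to the Mann-Whitney rank-sum statistic normalized by n1*n0.
    """
    s, y = _check_scores(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, s))


def bootstrap_ci(metric_fn, scores, labels, n_boot: int = 2000,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval over patient-level resamples.

    Resamples that lose a class (where the metric is undefined) are skipped
    and logged.
    """
    s, y = _check_scores(scores, labels)
    if s.size < 10:
        raise ValueError("bootstrap needs n >= 10")
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, s.size, s.size)
        try:
            vals.append(metric_fn(s[idx], y[idx]))
        except ValueError:
            skipped += 1
    if skipped:
        logger.info("bootstrap: skipped %d one-class resamples", skipped)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def operating_point(scores, labels, target_sensitivity: float = 0.7) -> float:
    """Largest threshold whose sensitivity meets the target on this set.

    Classification rule: score >= threshold -> positive.  Meant to be run
    on training scores and then frozen.  If the target is unreachable the
    returned threshold sits below the minimum score (everything positive)
    and a warning is emitted.
    """
    s, y = _check_scores(scores, labels)
    pos = s[y == 1]
    if pos.size == 0:
        raise ValueError("no positive cases")
    candidates = np.unique(s)[::-1]  # descending
    for thr in candidates:
        sens = float((pos >= thr).mean())
        if sens >= target_sensitivity:
            return float(thr)
    warnings.warn("target sensitivity unreachable; thresholding below the "
                  "minimum score", stacklevel=2)
    return float(s.min() - 1e-9)


@dataclass
class MetricReport:
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    brier: float | None = None
    calibration_curve: list[tuple[float, float, int]] = field(
        default_factory=list)

    @property
    def confusion(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def classification_metrics(scores, labels, threshold: float) -> MetricReport:
    """Confusion matrix and derived rates at a fixed threshold.

    Rates with an empty denominator are reported as None (undefined), never
    as NaN.
    """
    s, y = _check_scores(scores, labels)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())

    def rate(num, den):
        return num / den if den > 0 else None

    precision = rate(tp, tp + fp)
    recall = rate(tp, tp + fn)
    specificity = rate(tn, tn + fp)
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return MetricReport(
        threshold=float(threshold), tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / s.size, precision=precision, recall=recall,
        specificity=specificity, f1=f1,
    )


def calibration(scores, labels, n_bins: int = 10):
    """Equal-width reliability curve and the Brier score.

    Returns ``(curve, brier)`` where curve rows are
    (mean predicted, observed fraction, bin count); empty bins are skipped.
    """
    s, y = _check_scores(scores, labels)
    if s.size < n_bins:
        raise ValueError("need at least n_bins observations")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(s, edges[1:-1]), 0, n_bins - 1)
    curve = []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        curve.append((float(s[sel].mean()), float(y[sel].mean()),
                      int(sel.sum())))
    brier = float(((s - y) ** 2).mean())
    return curve, brier


def brier_score(scores, labels) -> float:
    s, y = _check_scores(scores, labels)
    return float(((s - y) ** 2).mean())


def isotonic_recalibrate(fit_scores, fit_labels, n_folds: int | None = None,
                         seed: int = 0):
    """Fit a non-decreasing score -> probability map (PAV) on training
    predictions; apply out-of-sample via the returned callable.

    With ``n_folds`` set, K maps are fitted on complementary folds and
    averaged — a cross-validated variant that damps the optimism of
    fitting the map on the very points it will be judged on.  One-class
    fit labels degenerate to a constant map (with a warning).
    """
    s, y = _check_scores(fit_scores, fit_labels)
    if s.size < 10:
        raise ValueError("isotonic recalibration needs >= 10 fit points")
    if len(np.unique(y)) < 2:
        warnings.warn("one-class fit labels: isotonic map is constant",
                      stacklevel=2)
        const = float(y.mean())
        return lambda x: np.full(np.asarray(x, dtype=float).shape, const)

    def fit_one(si, yi):
        iso = IsotonicRegression(y_min=0.0, y_max=1.0,
                                 out_of_bounds="clip")
        iso.fit(si, yi)
        return iso

    if n_folds is None:
        iso = fit_one(s, y)
        return lambda x: iso.predict(np.asarray(x, dtype=np.float64))

    rng = np.random.default_rng(seed)
    order = rng.permutation(s.size)
    folds = np.array_split(order, n_folds)
    models = []
    for held_out in folds:
        keep = np.setdiff1d(order, held_out)
        if len(np.unique(y[keep])) < 2:
            continue
        models.append(fit_one(s[keep], y[keep]))
    if not models:
        raise ValueError("every fold lost a class; reduce n_folds")

    def apply(x):
        x = np.asarray(x, dtype=np.float64)
        return np.mean([m.predict(x) for m in models], axis=0)

    return apply


def group_compare(scores, labels) -> tuple[float, float]:
    """Mann-Whitney p-value and Cohen's d between the two label groups."""
    s, y = _check_scores(scores, labels)
    a, b = s[y == 1], s[y == 0]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if a.size == b.size and np.allclose(np.sort(a), np.sort(b)):
        p = 1.0
    else:
        method = "exact" if min(a.size, b.size) <= 8 else "asymptotic"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method=method).pvalue)
    n1, n0 = a.size, b.size
    pooled_var = (((n1 - 1) * a.var(ddof=1) if n1 > 1 else 0.0)
                  + ((n0 - 1) * b.var(ddof=1) if n0 > 1 else 0.0))
    dof = n1 + n0 - 2
    pooled_sd = np.sqrt(pooled_var / dof) if dof > 0 else 0.0
    if pooled_sd == 0:
        if abs(a.mean() - b.mean()) < 1e-12:
            return p, 0.0
        raise ValueError("zero pooled SD with unequal means")
    d = float((a.mean() - b.mean()) / pooled_sd)
    return p, d


def evaluate_cohort(scores, labels, threshold: float,
                    n_boot: int = 2000, seed: int = 0) -> MetricReport:
    """Full metric report: discrimination + thresholded rates + calibration."""
    report = classification_metrics(scores, labels, threshold)
    report.auc = roc_auc(scores, labels)
    if len(np.asarray(scores)) >= 10:
        report.auc_ci = bootstrap_ci(roc_auc, scores, labels,
                                     n_boot=n_boot, seed=seed)
    curve, brier = calibration(scores, labels,
                               n_bins=min(10, len(np.asarray(scores))))
    report.calibration_curve = curve
    report.brier = brier
    return report
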