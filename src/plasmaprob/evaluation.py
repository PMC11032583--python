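"""Diagnostic-performance evaluation.

Confusion matrices and sensitivity/specificity/accuracy, with optional
exclusion of uncertain calls (posterior inside the 0.3–0.7 zone); empirical
ROC curves with trapezoidal AUC (identical to the rank statistic);
Youden-index cutoffs; stratified percentile bootstrap confidence intervals
(2000 replicates by default); and Cohen's d effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._rng import substream
from .errors import EvaluationError
from .models import ClassificationResult

__all__ = [
    "ConfusionMatrix",
    "PerformanceReport",
    "RocResult",
    "confusion",
    "metrics",
    "roc",
    "youden_cutoff",
    "bootstrap_ci",
    "cohens_d",
]


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    @property
    def n_classified(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceReport:
    """Sensitivity/specificity/accuracy; None marks an undefined metric."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    excluded_fraction: float = 0.0
    ci: dict | None = None  # metric -> (low, high), filled by callers


@dataclass
class RocResult:
    thresholds: np.ndarray
    sens_points: np.ndarray
    spec_points: np.ndarray
    auc: float
    youden_threshold: float
    youden_j: float
    ci_low: float | None = None
    ci_high: float | None = None


def confusion(y_true, results: Sequence[ClassificationResult] | np.ndarray,
              exclude_uncertain: bool = False) -> ConfusionMatrix:
    """Tally a confusion matrix from per-record classification results.

    ``y_true`` holds 0/1 truth (1 = positive). ``results`` may be
    ClassificationResult objects or a plain 0/1 prediction array (in which
    case nothing is ever excluded).
    """
    y = np.asarray(y_true).astype(int)
    if len(y) != len(results):
        raise EvaluationError("records and results length mismatch")
    if len(results) and isinstance(results[0], ClassificationResult):
        pred = np.array([1 if r.label == "positive" else 0 for r in results])
        unc = np.array([r.uncertain for r in results])
    else:
        pred = np.asarray(results).astype(int)
        unc = np.zeros(len(pred), dtype=bool)
    keep = ~unc if exclude_uncertain else np.ones(len(pred), dtype=bool)
    n_excluded = int((~keep).sum())
    y, pred = y[keep], pred[keep]
    return ConfusionMatrix(
        tp=int(((y == 1) & (pred == 1)).sum()),
        fp=int(((y == 0) & (pred == 1)).sum()),
        tn=int(((y == 0) & (pred == 0)).sum()),
        fn=int(((y == 1) & (pred == 0)).sum()),
        n_excluded=n_excluded,
    )


def metrics(cm: ConfusionMatrix) -> PerformanceReport:
    """Sensitivity, specificity, accuracy; undefined metrics become None."""
    pos, neg = cm.tp + cm.fn, cm.tn + cm.fp
    sens = cm.tp / pos if pos > 0 else None
    spec = cm.tn / neg if neg > 0 else None
    total = cm.n_classified
    acc = (cm.tp + cm.tn) / total if total > 0 else None
    denom = total + cm.n_excluded
    return PerformanceReport(
        sensitivity=sens, specificity=spec, accuracy=acc,
        excluded_fraction=cm.n_excluded / denom if denom else 0.0,
    )


def _oriented_scores(values, labels, orientation: str):
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("ROC needs both classes present")
    score = v if orientation == "positive_high" else -v
    return score, v, y


def roc(values, labels, orientation: str = "positive_high") -> RocResult:
    """Empirical ROC over all distinct thresholds, with trapezoidal AUC.

    ``orientation="positive_low"`` treats LOW values as indicating the
    positive class (as for the Abeta42/40 ratio). The trapezoidal AUC over
    the empirical curve equals the Mann–Whitney rank statistic scaled to
    [0, 1], with ties counted one half.
    """
    score, v, y = _oriented_scores(values, labels, orientation)
    order = np.argsort(-score, kind="mergesort")
    s, t = score[order], y[order]
    n_pos, n_neg = int(t.sum()), int(len(t) - t.sum())
    # cumulative counts at the end of each tie-block of distinct scores
    distinct = np.r_[np.diff(s) != 0, True]
    tp_cum = np.cumsum(t)[distinct]
    fp_cum = np.cumsum(1 - t)[distinct]
    sens = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    spec = 1.0 - fpr
    auc = float(np.trapezoid(sens, fpr))
    # Youden: maximize sens + spec - 1 over operating points; report the
    # midpoint of the flat threshold interval on the ORIGINAL value scale.
    j = sens + spec - 1.0
    best = int(np.argmax(j))
    s_distinct = s[distinct]
    if best == 0:
        # classify everything negative: threshold beyond the extreme score
        thr_score = s_distinct[0] + 1.0
    elif best == len(s_distinct):
        thr_score = s_distinct[-1] - 1.0
    else:
        thr_score = 0.5 * (s_distinct[best - 1] + s_distinct[best])
    thr = thr_score if orientation == "positive_high" else -thr_score
    thresholds = np.r_[s_distinct[0] + 1.0, s_distinct]
    if orientation == "positive_low":
        thresholds = -thresholds
    return RocResult(thresholds=thresholds, sens_points=sens,
                     spec_points=spec, auc=auc,
                     youden_threshold=float(thr), youden_j=float(j[best]))


def youden_cutoff(values, labels, orientation: str = "positive_high") -> float:
    """Threshold maximizing sensitivity + specificity − 1."""
    return roc(values, labels, orientation).youden_threshold


def bootstrap_ci(statistic: Callable, values, labels, B: int = 2000,
                 seed: int = 0, alpha: float = 0.05,
                 max_redraw_factor: int = 10) -> tuple[float, float]:
    """Percentile CI from B stratified bootstrap resamples.

    Resampling is within each class, so replicates keep both classes; a
    degenerate replicate (possible when a class's resample has zero
    variance and the statistic fails) is redrawn, with a cap of
    ``max_redraw_factor * B`` total attempts.
    """
    if B < 100:
        raise EvaluationError("B must be >= 100")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    rng = substream(seed, "bootstrap")
    idx_by_class = [np.flatnonzero(y == c) for c in np.unique(y)]
    stats_out = np.empty(B)
    attempts = 0
    i = 0
    while i < B:
        if attempts > max_redraw_factor * B:
            raise EvaluationError("too many degenerate bootstrap replicates")
        attempts += 1
        take = np.concatenate([rng.choice(ix, size=len(ix), replace=True)
                               for ix in idx_by_class])
        try:
            stats_out[i] = statistic(v[take], y[take])
        except EvaluationError:
            continue
        i += 1
    lo, hi = np.quantile(stats_out, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def cohens_d(values_a, values_b) -> float:
    """Standardized mean difference with the pooled (n−1-weighted) SD."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EvaluationError("Cohen's d needs n >= 2 per group")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0.0:
        raise EvaluationError("zero pooled SD: Cohen's d undefined")
    return float((a.mean() - b.mean()) / pooled)
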