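"""Diagnostic-validation statistics, implemented from first principles.

Everything here is the formulaic version of the statistics used to validate
one physiologic index against another: empirical ROC curves with the Youden
cutoff, 2x2 confusion metrics, Bland-Altman limits of agreement, the
two-way random-effects absolute-agreement intraclass correlation (ICC) with
its F-based confidence interval, Pearson/Spearman correlations, Fisher's
exact test by hypergeometric enumeration, and responder classification at
the 40 U resistance threshold.

Conventions (fixed throughout the package):

* the adverse condition (resistance >= threshold, MVO present) is the
  positive class, and a positive call is ``score >= cutoff``;
* Youden-index ties are broken toward the lowest cutoff;
* Fisher's two-sided p-value uses the point-probability method (sum of all
  tables no more probable than the observed one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateLabelsError,
    ImrAngioError,
    IncompleteDesignError,
    PairingError,
    UndefinedCorrelationError,
)


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float


@dataclass(frozen=True)
class ConfusionResult:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    pearson_r: Optional[float] = None
    spearman_rho: Optional[float] = None
    icc: Optional[float] = None
    icc_ci_low: Optional[float] = None
    icc_ci_high: Optional[float] = None
    icc_f: Optional[float] = None


@dataclass(frozen=True)
class ResponderResult:
    """Per-patient responder labels by both indices, and their disagreement."""

    patient_ids: tuple
    labels_imr: tuple       # "good" (post index < threshold) or "partial_poor"
    labels_imr_angio: tuple
    n_discordant: int
    misclassification_rate: float


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ImrAngioError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ImrAngioError(f"{name} contains non-finite values")
    return arr


def roc_and_youden(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC curve, trapezoidal AUC, and the Youden-optimal cutoff.

    Candidate cutoffs are the midpoints between consecutive sorted unique
    scores, plus -inf/+inf sentinels (call everything / call nothing).
    """
    s = _as_1d(scores, "scores")
    y = np.asarray(labels).astype(bool).ravel()
    if s.size != y.size:
        raise ImrAngioError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("need at least one positive and one negative label")

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    # positive call: score >= threshold
    sens = np.array([(s[y] >= t).sum() / n_pos for t in thresholds])
    spec = np.array([(s[~y] < t).sum() / n_neg for t in thresholds])

    # ROC points (FPR, TPR) traced in threshold order: thresholds ascend, so
    # reversing gives both FPR and TPR non-decreasing along the curve
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    j = sens + spec - 1.0
    best = int(np.flatnonzero(j == j.max())[0])  # ties -> lowest cutoff
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=float(thresholds[best]),
        youden_j=float(j[best]),
    )


def confusion_at_cutoff(
    scores: Sequence[float], labels: Sequence[int], cutoff: float
) -> ConfusionResult:
    """2x2 table and derived metrics for the call ``score >= cutoff``."""
    s = _as_1d(scores, "scores")
    y = np.asarray(labels).astype(bool).ravel()
    if s.size != y.size:
        raise ImrAngioError("scores and labels differ in length")
    call = s >= cutoff
    tp = int(np.sum(call & y))
    fp = int(np.sum(call & ~y))
    fn = int(np.sum(~call & y))
    tn = int(np.sum(~call & ~y))

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return ConfusionResult(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        accuracy=(tp + tn) / s.size,
    )


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Bias and 95% limits of agreement of the differences x - y."""
    a = _as_1d(x, "x")
    b = _as_1d(y, "y")
    if a.size != b.size:
        raise ImrAngioError("inputs differ in length")
    if a.size < 2:
        raise ImrAngioError("need at least two paired measurements")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def _midranks(x: np.ndarray) -> np.ndarray:
    """Average (mid) ranks, 1-based, ties sharing the mean of their positions."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero variance in one of the inputs")
    return float(xc @ yc) / (sx * sy)


def correlations(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """(Pearson r, Spearman rho); Spearman is Pearson on mid-ranks."""
    a = _as_1d(x, "x")
    b = _as_1d(y, "y")
    if a.size != b.size:
        raise ImrAngioError("inputs differ in length")
    if a.size < 3:
        raise ImrAngioError("need at least three pairs")
    return _pearson(a, b), _pearson(_midranks(a), _midranks(b))


def icc_absolute_agreement(
    ratings: Sequence[Sequence[float]], alpha: float = 0.05
) -> tuple[float, tuple[float, float], float]:
    """Two-way random-effects, single-rater, absolute-agreement ICC.

    ``ratings`` is an n-subjects x 2-raters table with no missing cells.
    Returns ``(icc, (ci_low, ci_high), F)`` where the confidence interval
    follows the F-distribution method for ICC(A,1) and F = MSR/MSE is the
    between-subjects test statistic.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise IncompleteDesignError("ratings must be an n x 2 table")
    if not np.all(np.isfinite(table)):
        raise IncompleteDesignError("ratings table has missing cells")
    n, k = table.shape
    if n < 3:
        raise IncompleteDesignError("need at least three subjects")

    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((table - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    # McGraw & Wong F-method interval for ICC(A,1)
    if mse == 0 and msc == msr:
        return 1.0, (1.0, 1.0), math.inf
    r = icc
    a = k * r / (n * (1.0 - r)) if r < 1.0 else math.inf
    b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r)) if r < 1.0 else math.inf
    if math.isinf(a):
        v = n - 1.0
    else:
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        v = num / den if den > 0 else n - 1.0
    f_low = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
    f_stat = msr / mse if mse > 0 else math.inf
    return float(icc), (float(lower), float(upper)), float(f_stat)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Enumerates the hypergeometric distribution of the top-left cell with all
    margins fixed and sums the point probabilities that do not exceed the
    observed table's (point-probability method).  Exact integer arithmetic.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or t.dtype.kind not in "iu":
        t = t.astype(float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
            raise ImrAngioError("table must be 2x2 non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n < 1:
        raise ImrAngioError("table must contain at least one observation")
    r1, c1 = a + b, a + c
    denom = math.comb(n, c1)

    def weight(k: int) -> int:  # numerator of P(X = k), over comb(n, c1)
        return math.comb(r1, k) * math.comb(n - r1, c1 - k)

    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    observed = weight(a)
    total = sum(w for k in range(lo, hi + 1) if (w := weight(k)) <= observed)
    return total / denom


def chi2_2x2(table: Sequence[Sequence[int]]) -> float:
    """Pearson chi-square p (no continuity correction) for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ImrAngioError("table must be 2x2 non-negative counts")
    n = t.sum()
    if n == 0:
        raise ImrAngioError("empty table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if np.any(expected == 0):
        raise ImrAngioError("degenerate margins")
    stat = float(((t - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, df=1))


def classify_responders(
    pre_panels,
    post_panels,
    threshold: float = 40.0,
) -> ResponderResult:
    """Label patients as good (post index < threshold) or partial/poor responders.

    Panels are sequences of :class:`~imrangio.indices.IndexPanel` for the
    infarct-related artery.  Each pre-PCI panel must have a matching post-PCI
    panel (same lesion).  Labels are assigned from the post-PCI value of each
    index; the misclassification rate is the fraction of patients whose
    IMR_angio label disagrees with their IMR label.
    """
    pre_by_id = {p.lesion_id: p for p in pre_panels}
    post_by_id = {p.lesion_id: p for p in post_panels}
    if set(pre_by_id) != set(post_by_id):
        missing = set(pre_by_id) ^ set(post_by_id)
        raise PairingError(f"unpaired lesions: {sorted(missing)}")
    if not pre_by_id:
        raise PairingError("no paired patients")

    ids, by_imr, by_angio = [], [], []
    for lesion_id in sorted(post_by_id):
        post = post_by_id[lesion_id]
        ids.append(lesion_id)
        by_imr.append("good" if post.IMR < threshold else "partial_poor")
        by_angio.append("good" if post.IMR_angio < threshold else "partial_poor")
    n_disc = sum(1 for u, v in zip(by_imr, by_angio) if u != v)
    return ResponderResult(
        patient_ids=tuple(ids),
        labels_imr=tuple(by_imr),
        labels_imr_angio=tuple(by_angio),
        n_discordant=n_disc,
        misclassification_rate=n_disc / len(ids),
    )
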