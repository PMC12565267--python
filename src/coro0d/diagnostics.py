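"""Diagnostic evaluation of lesion indices against revascularization labels.

Implements the evaluation battery used to benchmark a continuous diagnostic
index: empirical ROC curve and AUC (Mann-Whitney with ties counted 1/2),
Youden-optimal cutoff, confusion-matrix rates, DeLong's paired AUC test
(placement-value covariance), Bland-Altman agreement, and Pearson correlation.

Orientation matters: a resistance-type index (cHSR, delta_P) is positive when
HIGH, a pressure-ratio index (FFR-type) is positive when LOW. `LabeledScores`
carries this as a flag; internally scores are oriented so that higher means
more positive, and cutoffs are mapped back to the original scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LabeledScores",
    "DiagnosticReport",
    "roc_auc",
    "roc_points",
    "youden_cutoff",
    "confusion_metrics",
    "delong_test",
    "bland_altman",
    "pearson",
    "evaluate_index",
]


@dataclass(frozen=True)
class LabeledScores:
    """Per-lesion scores with binary labels (positive = revascularized)."""

    scores: np.ndarray
    labels: np.ndarray
    higher_is_positive: bool = True

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.ndim != 1 or scores.shape != labels.shape:
            raise ValueError("scores and labels must be 1-D of equal length")
        if not np.all(np.isin(labels, (0, 1))):
            raise ValueError("labels must be binary (0/1)")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(int))

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(self.labels.size - self.labels.sum())

    def oriented(self) -> np.ndarray:
        """Scores transformed so that higher means more positive."""
        return self.scores if self.higher_is_positive else -self.scores

    def _require_both_classes(self):
        if self.n_positive == 0 or self.n_negative == 0:
            raise ValueError("both classes must be present")


def roc_auc(data: LabeledScores) -> Tuple[pd.DataFrame, float]:
    """Empirical ROC points over all observed thresholds, and the AUC.

    The AUC equals the Mann-Whitney statistic: the probability that a random
    positive outscores a random negative, ties counted 1/2.
    """
    data._require_both_classes()
    s = data.oriented()
    y = data.labels
    n1, n0 = data.n_positive, data.n_negative
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return roc_points(data), float(auc)


def roc_points(data: LabeledScores) -> pd.DataFrame:
    """Sensitivity/specificity at every observed threshold (rule: score >= t
    positive on the oriented scale)."""
    s = data.oriented()
    y = data.labels
    thresholds = np.unique(s)
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for k, t in enumerate(thresholds):
        pred = s >= t
        sens[k] = np.mean(pred[y == 1]) if data.n_positive else np.nan
        spec[k] = np.mean(~pred[y == 0]) if data.n_negative else np.nan
    cut = thresholds if data.higher_is_positive else -thresholds
    return pd.DataFrame(
        {"cutoff": cut, "sensitivity": sens, "specificity": spec,
         "youden_j": sens + spec - 1.0}
    )


def youden_cutoff(data: LabeledScores) -> Tuple[float, float]:
    """The cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Thresholds are evaluated at the observed score values with the
    positivity rule score >= cutoff (score <= cutoff when the orientation is
    flipped); ties are broken toward the smallest original-scale cutoff.
    """
    data._require_both_classes()
    pts = roc_points(data).sort_values("cutoff", kind="stable")
    j = pts["youden_j"].to_numpy()
    best = int(np.argmax(j))  # first (= smallest cutoff) among maxima
    return float(pts["cutoff"].to_numpy()[best]), float(j[best])


def confusion_metrics(data: LabeledScores, cutoff: float) -> Dict[str, Optional[float]]:
    """Sensitivity/specificity/accuracy/PPV/NPV (percent) at a cutoff.

    A rate with an empty denominator is reported as None, not 0.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if data.higher_is_positive:
        pred = data.scores >= cutoff
    else:
        pred = data.scores <= cutoff
    y = data.labels.astype(bool)
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))

    def rate(num, den):
        return 100.0 * num / den if den > 0 else None

    n = tp + fn + tn + fp
    return {
        "sensitivity": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "accuracy": rate(tp + tn, n),
        "ppv": rate(tp, tp + fp),
        "npv": rate(tn, tn + fn),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def _placements(scores: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (V10 per positive, V01 per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # psi(x, y) = 1 if x > y, 1/2 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01


def delong_test(a: LabeledScores, b: LabeledScores) -> Tuple[float, Optional[float]]:
    """DeLong's test for two correlated AUCs measured on the same lesions.

    Returns (z, two-sided p). Requires identical labels (paired design). A
    degenerate variance with a nonzero AUC difference yields p = None; two
    identical score vectors yield (0, 1).
    """
    a._require_both_classes()
    if a.labels.shape != b.labels.shape or np.any(a.labels != b.labels):
        raise ValueError("paired DeLong test requires identical labels")
    sa, sb = a.oriented(), b.oriented()
    y = a.labels
    m = a.n_positive
    n = a.n_negative
    v10_a, v01_a = _placements(sa, y)
    v10_b, v01_b = _placements(sb, y)
    auc_a = v10_a.mean()
    auc_b = v10_b.mean()
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = auc_a - auc_b
    if var <= 1e-15:
        if abs(diff) <= 1e-15:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), None
    z = diff / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bland_altman(x, y) -> Tuple[float, Tuple[float, float]]:
    """Bland-Altman bias and 95% limits of agreement for paired measurements.

    differences d = x - y; bias = mean(d); limits = bias +/- 1.96 * sd(d)
    with the sample (n-1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def pearson(x, y) -> Tuple[float, float]:
    """Pearson correlation with a t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson needs two equal 1-D arrays of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson is undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class DiagnosticReport:
    """Cohort-level evaluation of one index (optionally vs comparators)."""

    index_name: str
    auc: float
    optimal_cutoff: float
    youden_j: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    n_positive: int
    n_negative: int
    delong: Dict[str, Tuple[float, Optional[float]]] = field(default_factory=dict)
    bland_altman: Optional[Tuple[float, Tuple[float, float]]] = None
    pearson_r: Optional[float] = None
    pearson_p: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "index": self.index_name,
            "auc": self.auc,
            "optimal_cutoff": self.optimal_cutoff,
            "youden_j": self.youden_j,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
            "ppv_pct": self.ppv,
            "npv_pct": self.npv,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }
        if self.delong:
            d["delong"] = {k: {"z": z, "p": p} for k, (z, p) in self.delong.items()}
        if self.bland_altman is not None:
            bias, (lo, hi) = self.bland_altman
            d["bland_altman"] = {"bias": bias, "lower_limit": lo, "upper_limit": hi}
        if self.pearson_r is not None:
            d["pearson"] = {"r": self.pearson_r, "p": self.pearson_p}
        return d


def evaluate_index(
    data: LabeledScores,
    index_name: str = "index",
    comparators: Optional[Dict[str, LabeledScores]] = None,
    agreement_reference: Optional[np.ndarray] = None,
) -> DiagnosticReport:
    """Full single-index evaluation at the Youden-optimal cutoff.

    `comparators` adds paired DeLong comparisons; `agreement_reference` (same
    quantity measured another way, e.g. invasive FFR vs FFR_CFD) adds
    Bland-Altman and Pearson agreement of the raw scores.
    """
    _, auc = roc_auc(data)
    cutoff, j = youden_cutoff(data)
    cm = confusion_metrics(data, cutoff)
    report = DiagnosticReport(
        index_name=index_name,
        auc=auc,
        optimal_cutoff=cutoff,
        youden_j=j,
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        accuracy=cm["accuracy"],
        ppv=cm["ppv"],
        npv=cm["npv"],
        n_positive=data.n_positive,
        n_negative=data.n_negative,
    )
    for name, comp in (comparators or {}).items():
        report.delong[name] = delong_test(data, comp)
    if agreement_reference is not None:
        ref = np.asarray(agreement_reference, dtype=float)
        report.bland_altman = bland_altman(data.scores, ref)
        report.pearson_r, report.pearson_p = pearson(data.scores, ref)
    return report
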