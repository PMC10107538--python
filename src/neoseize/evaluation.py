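"""Performance metrics, confidence intervals and model-comparison statistics.

Includes the operating-point reconstruction used for verification: given a
published sensitivity/specificity pair and the class sizes, rebuild the
confusion matrix by nearest-integer rounding and recompute MCC/PPV/NPV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "mcc",
    "confusion_from_rates",
    "equal_ss_threshold",
    "auc",
    "williams_test",
    "cohens_kappa",
    "bootstrap_ci",
    "mcc_at_equal_ss",
    "metric_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.tp / self.n_pos if self.n_pos else float("nan")

    @property
    def specificity_pct(self) -> float:
        return 100.0 * self.tn / self.n_neg if self.n_neg else float("nan")

    @property
    def ppv_pct(self) -> float:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def npv_pct(self) -> float:
        d = self.tn + self.fn
        return 100.0 * self.tn / d if d else float("nan")


@dataclass(frozen=True)
class MetricReport:
    mcc: float
    mcc_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    sensitivity_pct: float
    specificity_pct: float
    ppv_pct: float
    npv_pct: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "mcc": self.mcc,
            "mcc_ci": list(self.mcc_ci),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "ppv_pct": self.ppv_pct,
            "npv_pct": self.npv_pct,
            "threshold": self.threshold,
        }


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; zero by convention when any marginal
    is empty."""
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / float(np.sqrt(denom))


def confusion_from_rates(
    sensitivity_pct: float, specificity_pct: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Rebuild a confusion matrix from printed rates by nearest-integer rounding."""
    if not (0 <= sensitivity_pct <= 100 and 0 <= specificity_pct <= 100):
        raise ValueError("rates must lie in [0, 100]")
    tp = int(round(sensitivity_pct / 100.0 * n_pos))
    tn = int(round(specificity_pct / 100.0 * n_neg))
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


def _confusion_at(probs: np.ndarray, labels: np.ndarray, thr: float) -> ConfusionMatrix:
    pred = probs >= thr
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def equal_ss_threshold(probs, labels) -> tuple[float, ConfusionMatrix]:
    """Operating point of (approximately) equal sensitivity and specificity.

    Candidate thresholds are midpoints between sorted unique probabilities
    (plus the extremes); the threshold minimizing |sensitivity − specificity|
    wins, ties broken toward higher sensitivity.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(probs)
    if uniq.size == 1:
        warnings.warn("all probabilities identical; degenerate threshold 0.5", stacklevel=2)
        return 0.5, _confusion_at(probs, labels, 0.5)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1e-12], mids, [uniq[-1] + 1e-12]])
    best_gap = np.inf
    best_sens = -np.inf
    best_cm: ConfusionMatrix | None = None
    best_thr = 0.5
    for thr in candidates:
        cm = _confusion_at(probs, labels, thr)
        gap = abs(cm.sensitivity_pct - cm.specificity_pct)
        if gap < best_gap - 1e-12 or (
            abs(gap - best_gap) <= 1e-12 and cm.sensitivity_pct > best_sens + 1e-12
        ):
            best_gap, best_sens, best_cm, best_thr = gap, cm.sensitivity_pct, cm, float(thr)
    return best_thr, best_cm


def auc(probs, labels) -> float:
    """Rank-based (Mann–Whitney) AUC with half-credit for ties."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC requires both classes")
    ranks = spstats.rankdata(probs)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def williams_test(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Hotelling–Williams t test for two dependent correlations sharing a
    variable; returns (t, two-sided p) with n − 3 degrees of freedom."""
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    det = 1.0 - r1**2 - r2**2 - r12**2 + 2.0 * r1 * r2 * r12
    rbar = 0.5 * (r1 + r2)
    denom = 2.0 * ((n - 1.0) / (n - 3.0)) * det + rbar**2 * (1.0 - r12) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation structure")
    t = (r1 - r2) * np.sqrt((n - 1.0) * (1.0 + r12) / denom)
    p = 2.0 * spstats.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


def cohens_kappa(a, b) -> float:
    """Cohen's kappa for two binary label vectors."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    po = float(np.mean(a == b))
    pe = float(np.mean(a) * np.mean(b) + np.mean(1 - a) * np.mean(1 - b))
    if pe == 1.0:
        # both raters constant: full credit only if they agree everywhere
        return 1.0 if po == 1.0 else float("nan")
    return (po - pe) / (1.0 - pe)


def bootstrap_ci(
    probs,
    labels,
    metric,
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Stratified subject-level percentile bootstrap.

    *metric* is called as ``metric(probs, labels)`` on each resample (any
    threshold-dependent metric must refit its threshold inside the callable).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.size < 20:
        raise ValueError("bootstrap CI requires at least 20 subjects")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        stats[b] = metric(probs[idx], labels[idx])
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def mcc_at_equal_ss(probs, labels) -> float:
    """MCC at the equal-sensitivity/specificity operating point."""
    _, cm = equal_ss_threshold(probs, labels)
    return mcc(cm)


def metric_report(probs, labels, n_boot: int = 2000, seed: int | None = None) -> MetricReport:
    """Full report at the equal-sensitivity/specificity operating point."""
    thr, cm = equal_ss_threshold(probs, labels)
    point_mcc = mcc(cm)
    point_auc = auc(probs, labels)
    mcc_ci = bootstrap_ci(probs, labels, mcc_at_equal_ss, n_boot=n_boot, seed=seed)
    auc_ci = bootstrap_ci(probs, labels, lambda p, y: auc(p, y), n_boot=n_boot, seed=seed)
    # percentile intervals are widened, if needed, to contain the point estimate
    mcc_ci = (min(mcc_ci[0], point_mcc), max(mcc_ci[1], point_mcc))
    auc_ci = (min(auc_ci[0], point_auc), max(auc_ci[1], point_auc))
    return MetricReport(
        mcc=point_mcc,
        mcc_ci=mcc_ci,
        auc=point_auc,
        auc_ci=auc_ci,
        sensitivity_pct=cm.sensitivity_pct,
        specificity_pct=cm.specificity_pct,
        ppv_pct=cm.ppv_pct,
        npv_pct=cm.npv_pct,
        threshold=thr,
    )
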