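"""Model evaluation: discrimination, calibration, clinical utility, ICC.

Discrimination is the rank-based (trapezoidal) AUC with ties given half
credit.  Operating metrics come from a confusion matrix at a threshold
chosen once on training data by the Youden index (max sensitivity +
specificity - 1) and then frozen for every evaluation set.  Clinical
utility is decision-curve net benefit, NB(pt) = TP/n - (FP/n) *
pt/(1-pt).  Segmentation reproducibility uses the two-way random-effects,
absolute-agreement, single-measurement ICC(2,1) with an F-based 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "RocResult",
    "DcaResult",
    "IccResult",
    "auc",
    "youden_threshold",
    "operating_metrics",
    "roc_evaluation",
    "calibration_curve",
    "decision_curve",
    "icc_agreement",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return labels


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Trapezoidal ROC AUC; equals the tie-corrected Mann-Whitney statistic."""
    labels = _check_binary(np.asarray(labels))
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold maximising sensitivity + specificity - 1 on these data.

    Classification rule is score >= threshold; among ties the smallest
    threshold is returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and (best_t is None or t < best_t)):
            best_t, best_j = t, j
    return float(best_t)


def operating_metrics(scores, labels, threshold: float) -> Dict[str, float]:
    """sens/spec/accuracy/PPV/NPV at a frozen threshold (score >= t positive).

    A PPV or NPV with a zero denominator is reported as NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    n = len(labels)
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / n,
        "ppv": tp / (tp + fp) if tp + fp > 0 else float("nan"),
        "npv": tn / (tn + fn) if tn + fn > 0 else float("nan"),
        "threshold": float(threshold),
    }


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating_threshold: float
    operating: Dict[str, float]


def roc_evaluation(scores, labels, threshold: Optional[float] = None) -> RocResult:
    """Full ROC summary; the operating threshold defaults to in-set Youden."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(np.asarray(labels))
    fpr, tpr, thr = roc_curve(labels, scores)
    t = youden_threshold(scores, labels) if threshold is None else float(threshold)
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc(scores, labels),
        operating_threshold=t,
        operating=operating_metrics(scores, labels, t),
    )


def calibration_curve(probs, labels, n_bins: int = 10) -> pd.DataFrame:
    """Reliability curve on equal-width probability bins; empty bins omitted.

    Returns per-bin mean predicted probability, observed event fraction
    and count; counts sum to n.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append((float(probs[sel].mean()), float(labels[sel].mean()), int(sel.sum())))
    return pd.DataFrame(rows, columns=["mean_predicted", "observed_fraction", "count"])


@dataclass
class DcaResult:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.treat_none is None:
            self.treat_none = np.zeros_like(self.thresholds)


def decision_curve(probs, labels, thresholds: Optional[Sequence[float]] = None) -> DcaResult:
    """Decision-curve analysis over a threshold-probability grid.

    NB(pt) = TP/n - (FP/n) * pt/(1-pt) with prob >= pt classified
    positive; treat-all classifies everyone positive; treat-none is the
    zero reference.
    """
    probs = np.asarray(probs, dtype=float)
    labels = _check_binary(np.asarray(labels))
    thresholds = np.arange(0.01, 1.0, 0.01) if thresholds is None else np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie in (0, 1)")
    n = len(labels)
    prevalence = labels.mean()
    nb = np.empty_like(thresholds)
    ta = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        pred = probs >= pt
        tp = (pred & (labels == 1)).sum() / n
        fp = (pred & (labels == 0)).sum() / n
        w = pt / (1.0 - pt)
        nb[i] = tp - fp * w
        ta[i] = prevalence - (1.0 - prevalence) * w
    return DcaResult(thresholds=thresholds, net_benefit=nb, treat_all=ta)


@dataclass
class IccResult:
    icc: float
    ci: Tuple[float, float]
    label: str


def _icc_label(v: float) -> str:
    if v <= 0.40:
        return "poor"
    if v <= 0.60:
        return "moderate"
    if v <= 0.80:
        return "good"
    return "excellent"


def icc_agreement(ratings: np.ndarray) -> IccResult:
    """ICC(2,1) reliability of a subjects x raters matrix.

    Two-way random effects, absolute agreement, single measurement, with
    the F-based 95% CI; the qualitative label uses the conventional bins
    (<=0.40 poor, 0.40-0.60 moderate, 0.60-0.80 good, >0.80 excellent).
    """
    import pingouin as pg

    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] < 2 or ratings.shape[0] < 5:
        raise ValueError("need a subjects x raters matrix with >= 5 subjects, >= 2 raters")
    if np.var(ratings.mean(axis=1)) == 0:
        raise ValueError("zero between-subject variance: ICC undefined")
    n, k = ratings.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": ratings.ravel(),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    table = table.set_index("Type")
    row = table.loc["ICC(A,1)"] if "ICC(A,1)" in table.index else table.loc["ICC2"]
    icc = float(row["ICC"])
    ci_col = "CI95" if "CI95" in row.index else "CI95%"
    lo, hi = (float(v) for v in row[ci_col])
    return IccResult(icc=icc, ci=(lo, hi), label=_icc_label(icc))
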