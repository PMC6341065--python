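"""Classifier-quality metrics: ROC AUC, the discrimination threshold tau,
and the confusion-matrix summaries (FDR, Sn, Sp, ACC, MCC).

AUC is the Mann-Whitney statistic (ties credited 0.5 per pair), shared with
the single-gene ranking in :mod:`flowps.feature_selection`.  tau is chosen
to minimize FP + FN, with a sample called a responder when its score is
strictly above tau.  "FDR" here is the per-classifier false-discovery
fraction FP/(FP+TP) at tau, not a multiple-testing rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import RESPONDER


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D vectors of equal length")
    return scores, labels


def mann_whitney_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC of ``scores`` for the boolean ``positive`` mask; 0.5 credit per tie."""
    n1 = int(positive.sum())
    n0 = positive.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[positive].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc(scores, labels) -> float:
    """Mann-Whitney ROC AUC of ``scores`` as evidence for label == 100."""
    scores, labels = _check_scores_labels(scores, labels)
    return mann_whitney_auc(scores, labels == RESPONDER)


def threshold_candidates(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores plus below-min/above-max
    sentinels, so 'call everything' and 'call nothing' are both reachable."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2
    return np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))


def optimal_threshold(scores, labels) -> float:
    """The cutoff tau minimizing FP + FN under the rule score > tau => responder.

    Ties in the achieved error count are broken toward the smallest tau.
    """
    scores, labels = _check_scores_labels(scores, labels)
    pos = labels == RESPONDER
    if pos.all() or not pos.any():
        raise ValueError("optimal_threshold needs both classes present")
    best_tau, best_err = None, None
    for tau in threshold_candidates(scores):
        called = scores > tau
        err = int((called & ~pos).sum() + (~called & pos).sum())
        if best_err is None or err < best_err:
            best_tau, best_err = float(tau), err
    return best_tau


@dataclass(frozen=True)
class MetricsReport:
    """Point metrics for one score vector at one threshold."""

    auc: float
    tau: float
    fdr: float
    sn: float
    sp: float
    acc: float
    mcc: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "fdr": self.fdr, "sn": self.sn, "sp": self.sp,
            "acc": self.acc, "mcc": self.mcc, "tau": self.tau, "n": self.n,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


def confusion_metrics(scores, labels, tau: float) -> MetricsReport:
    """Threshold at tau (score > tau => responder) and derive all metrics.

    Zero-denominator conventions: MCC = 0 when any marginal is empty,
    FDR = 0 when nothing is called positive.  AUC is NaN if only one class
    is present.
    """
    scores, labels = _check_scores_labels(scores, labels)
    pos = labels == RESPONDER
    called = scores > tau
    tp = int((called & pos).sum())
    fp = int((called & ~pos).sum())
    tn = int((~called & ~pos).sum())
    fn = int((~called & pos).sum())
    n = tp + fp + tn + fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / n if n else 0.0
    fdr = fp / (fp + tp) if fp + tp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    try:
        auc = roc_auc(scores, labels)
    except ValueError:
        auc = float("nan")
    return MetricsReport(
        auc=auc, tau=float(tau), fdr=fdr, sn=sn, sp=sp, acc=acc,
        mcc=float(mcc), tp=tp, fp=fp, tn=tn, fn=fn,
    )


def evaluate_scores(scores, labels) -> MetricsReport:
    """Convenience: pick the optimal tau, then report all metrics at it."""
    tau = optimal_threshold(scores, labels)
    return confusion_metrics(scores, labels, tau)
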