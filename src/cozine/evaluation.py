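"""Structure-recovery metrics over unordered node pairs.

An estimated graph is compared with the generating one through the
confusion table of its ``p(p-1)/2`` node pairs, from which TPR/FPR, ROC
curves with trapezoidal AUC, and Matthews' correlation coefficient are
computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "mcc", "roc_curve", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Edge confusion counts over unordered node pairs (i < j)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def fpr(self) -> float:
        d = self.tn + self.fp
        return self.fp / d if d else float("nan")


def _check_adjacency(A: np.ndarray, name: str) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square, got {A.shape}")
    if not np.array_equal(A, A.T):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
    return A != 0


def confusion(estimate: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Confusion counts of estimated vs true edges over unordered pairs."""
    E = _check_adjacency(estimate, "estimate")
    T = _check_adjacency(truth, "truth")
    if E.shape != T.shape:
        raise ValueError(f"shape mismatch: {E.shape} vs {T.shape}")
    iu = np.triu_indices(E.shape[0], k=1)
    e, t = E[iu], T[iu]
    return ConfusionCounts(
        tp=int(np.sum(e & t)),
        fp=int(np.sum(e & ~t)),
        tn=int(np.sum(~e & ~t)),
        fn=int(np.sum(~e & t)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient,
    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``, in [-1, 1].

    When any denominator factor is zero the score is undefined; the
    standard convention of returning 0 is used.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


def roc_curve(
    path: np.ndarray | list[np.ndarray], truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points of a path of graphs, anchored at (0,0) and (1,1).

    ``path`` is a sequence of adjacency matrices ordered by decreasing
    penalty (growing graphs).  The curve is sorted by FPR and made
    non-decreasing in TPR (staircase), the convention for scoring
    regularization paths.
    """
    T = _check_adjacency(truth, "truth")
    iu = np.triu_indices(T.shape[0], k=1)
    t = T[iu]
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must have at least one edge and one non-edge")
    fprs, tprs = [0.0], [0.0]
    for A in path:
        c = confusion(A, truth)
        fprs.append(c.fpr)
        tprs.append(c.tpr)
    fprs.append(1.0)
    tprs.append(1.0)
    fpr = np.asarray(fprs)
    tpr = np.asarray(tprs)
    order = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order], tpr[order]
    tpr = np.maximum.accumulate(tpr)
    return fpr, tpr


def roc_auc(path: np.ndarray | list[np.ndarray], truth: np.ndarray) -> float:
    """Trapezoidal area under the path's ROC curve, in [0, 1]."""
    fpr, tpr = roc_curve(path, truth)
    return float(np.trapezoid(tpr, fpr))
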