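"""Evaluation measures: Q-scores, MAE, Pearson correlation, ROC summaries.

Q3 is the fraction of residues whose 3-state secondary structure is
predicted correctly, pooled over a dataset; QH/QE/QC restrict the
denominator to residues observed in one class.  MAE and the Pearson
correlation assess the scalar properties on their [0, 1] scales.  ROC
summaries for the OMP benchmark follow the instance-count convention:
true-positive counts at fixed numbers of tolerated false positives.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import auc, roc_curve

from .struct_props import SS_CLASSES


def q_scores(true_ss: str, pred_ss: str) -> dict[str, float]:
    """Pooled Q3 plus per-class QH, QE, QC.

    Accepts concatenated 3-state strings; a class absent from the truth
    yields ``nan`` for its Q score.
    """
    if len(true_ss) != len(pred_ss):
        raise ValueError("secondary-structure strings differ in length")
    if not true_ss:
        raise ValueError("empty input")
    t = np.frombuffer(true_ss.encode(), dtype=np.uint8)
    p = np.frombuffer(pred_ss.encode(), dtype=np.uint8)
    correct = t == p
    out = {"Q3": float(correct.mean())}
    for cls in SS_CLASSES:  # C, E, H
        mask = t == ord(cls)
        out[f"Q{cls}"] = float(correct[mask].mean()) if mask.any() else float("nan")
    return out


def mae(predicted: np.ndarray, true: np.ndarray) -> float:
    """Mean absolute error between prediction scores and true values."""
    f = np.asarray(predicted, dtype=float)
    y = np.asarray(true, dtype=float)
    if f.shape != y.shape or f.size == 0:
        raise ValueError("inputs must be nonempty and of equal shape")
    return float(np.mean(np.abs(f - y)))


def pcc(predicted: np.ndarray, true: np.ndarray) -> float:
    """Pearson's correlation coefficient."""
    f = np.asarray(predicted, dtype=float)
    y = np.asarray(true, dtype=float)
    if f.shape != y.shape or f.size < 2:
        raise ValueError("need at least two paired values")
    return float(stats.pearsonr(f, y).statistic)


def roc_points(scores: np.ndarray, labels: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, float]:
    """Full ROC step curve (rates) and its area under the curve."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC needs both positive and negative labels")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return fpr, tpr, float(auc(fpr, tpr))


def tp_at_fp_counts(scores: np.ndarray, labels: np.ndarray,
                    fp_cutoffs: list[int]) -> dict[int, int]:
    """True-positive counts before exceeding each false-positive budget.

    Items are ranked by score descending (ties broken by label so that
    negatives are counted first, the conservative order); for each cutoff
    N the value is the number of true positives seen while at most N false
    positives have accumulated.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.lexsort((labels, -scores))  # desc score; negatives first
    cum_tp = 0
    cum_fp = 0
    out = {n: 0 for n in fp_cutoffs}
    for idx in order:
        if labels[idx] == 1:
            cum_tp += 1
        else:
            cum_fp += 1
        for n in fp_cutoffs:
            if cum_fp <= n:
                out[n] = max(out[n], cum_tp)
    return out
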