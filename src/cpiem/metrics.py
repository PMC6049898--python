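"""Detection-performance metrics and diagnostic statistics.

ROC conventions: the positive class is "cooperative"; FPR(a) = N_FP(a)/N_nc
and TPR(a) = N_TP(a)/N_c as the threshold a sweeps over the unique score
values.  All observations sharing a score enter at a single threshold, so
the trapezoidal area under the curve equals the Mann-Whitney U statistic
normalized by N_c * N_nc (ties counted one half).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm

POSITIVE_LABEL = "cooperative"


def _as_binary(labels) -> np.ndarray:
    a = np.asarray(labels)
    if a.dtype.kind in "bif":
        y = a.astype(bool)
    else:
        y = a == POSITIVE_LABEL
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y.astype(int)


@dataclass
class RocCurve:
    """ROC curve: thresholds (descending; leading +inf sentinel), FPR, TPR, auROC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


@dataclass
class PrCurve:
    """Precision-recall curve with step-wise integrated area (average precision)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    area: float


def roc_curve(labels, scores) -> RocCurve:
    """ROC curve of cooperative-vs-non-cooperative scores.

    ``labels`` may be booleans/0-1 or the strings "cooperative" /
    "non-cooperative".  Raises if either class is absent or lengths differ.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    return RocCurve(
        thresholds=thr, fpr=fpr, tpr=tpr, auroc=float(_skm.roc_auc_score(y, s))
    )


def precision_recall_curve(labels, scores) -> PrCurve:
    """Precision-recall curve; area is the step-wise integral (average precision)."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    prec, rec, thr = _skm.precision_recall_curve(y, s)
    return PrCurve(
        thresholds=thr,
        precision=prec,
        recall=rec,
        area=float(_skm.average_precision_score(y, s)),
    )


def wilcoxon_rank_sum(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration of the U null distribution when min(n, m) <= 8 and no
    value is shared across the samples; normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.intersect1d(a, b).size > 0 or np.unique(
        np.concatenate([a, b])
    ).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def _quantile_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(v, [i / n_bins for i in range(1, n_bins)])
    return np.digitize(v, edges)


def mutual_information(x, y, n_bins: int = 4) -> float:
    """Plug-in mutual information (bits) on equal-frequency quantile bins.

    Quantile binning keeps the estimate robust to the heavy right tails of
    ChIP-seq intensities.  A constant input collapses into one bin and
    yields 0 bits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < n_bins * n_bins:
        raise ValueError(f"need at least n_bins^2 = {n_bins * n_bins} samples")
    bx = _quantile_bins(x, n_bins)
    by = _quantile_bins(y, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(
        (joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])).sum()
    )


def pearson_r_squared(x, y) -> float:
    """Squared Pearson correlation; errors on constant input or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def write_roc_table(curve: RocCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
    ).to_csv(path, sep="\t", index=False)


def write_pr_table(curve: PrCurve, path: str | Path) -> None:
    n = len(curve.thresholds)
    pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "precision": curve.precision[:n],
            "recall": curve.recall[:n],
        }
    ).to_csv(path, sep="\t", index=False)
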