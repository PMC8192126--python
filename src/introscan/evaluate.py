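"""Classifier scoring: confusion counts, derived metrics and curves.

The positive condition is always AI.  Metrics with a zero denominator
are reported as NaN rather than coerced to 0.  Curves are computed at
every distinct predicted probability, so the threshold-0.5 operating
point is always a member of each sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from introscan.simulate.params import SelectionParams


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts at the rule Pr[AI] > threshold (positive = AI)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    call = p > threshold
    return ConfusionCounts(
        TP=int(np.sum(call & (y == 1))),
        FP=int(np.sum(call & (y == 0))),
        TN=int(np.sum(~call & (y == 0))),
        FN=int(np.sum(~call & (y == 1))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Precision, NPV, TPR, FPR, F1, MCC and unit-normalised MCC.

    The normalised MCC is (MCC + 1) / 2, so 0.5 corresponds to random
    guessing and 1.0 to perfect prediction.
    """
    precision = _safe_div(c.TP, c.TP + c.FP)
    npv = _safe_div(c.TN, c.TN + c.FN)
    tpr = _safe_div(c.TP, c.TP + c.FN)
    fpr = _safe_div(c.FP, c.FP + c.TN)
    f1 = (
        _safe_div(2 * precision * tpr, precision + tpr)
        if not (math.isnan(precision) or math.isnan(tpr))
        else float("nan")
    )
    mcc_den = math.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = (c.TP * c.TN - c.FP * c.FN) / mcc_den if mcc_den > 0 else float("nan")
    return {
        "precision": precision,
        "NPV": npv,
        "TPR": tpr,
        "FPR": fpr,
        "F1": f1,
        "MCC": mcc,
        "MCC_normalised": (mcc + 1) / 2 if not math.isnan(mcc) else float("nan"),
        "accuracy": _safe_div(c.TP + c.TN, c.total),
    }


def curves(
    probs: np.ndarray,
    labels: np.ndarray,
    negatives: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """ROC, precision-recall and MCC-F1 point sequences.

    Thresholds are swept over every distinct predicted probability
    (plus the extremes), covering false-positive rates from 0 to 100%.
    ``negatives`` optionally restricts the condition-negative items to
    a subset (boolean mask over items with label 0), e.g. "sweep only"
    or "DFE only"; positives are always kept.

    Returns arrays ``thresholds, FPR, TPR, precision, recall, MCC, F1``
    plus the scalar ``mccf1_score`` summarising distance to the perfect
    (1, 1) corner of MCC-F1 space.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if negatives is not None:
        keep = (y == 1) | np.asarray(negatives, dtype=bool)
        p, y = p[keep], y[keep]
    if y.min() == y.max():
        raise ValueError("need at least one item of each class")
    thresholds = np.concatenate([[-np.inf], np.unique(p), [np.inf]])
    rows = {k: [] for k in ("FPR", "TPR", "precision", "recall", "MCC", "F1")}
    for t in thresholds:
        mm = metrics(confusion(p, y, threshold=t))
        rows["FPR"].append(mm["FPR"])
        rows["TPR"].append(mm["TPR"])
        rows["precision"].append(mm["precision"])
        rows["recall"].append(mm["TPR"])
        rows["MCC"].append(mm["MCC_normalised"])
        rows["F1"].append(mm["F1"])
    out = {k: np.asarray(v) for k, v in rows.items()}
    out["thresholds"] = thresholds
    ok = ~(np.isnan(out["MCC"]) | np.isnan(out["F1"]))
    if ok.any():
        d = np.hypot(1 - out["MCC"][ok], 1 - out["F1"][ok])
        out["mccf1_score"] = float(1 - d.mean() / math.sqrt(2))
    else:
        out["mccf1_score"] = float("nan")
    return out


def roc_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (rank statistic, ties handled)."""
    from scipy.stats import rankdata

    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        return float("nan")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def prediction_grid(
    probs: np.ndarray,
    params: list[SelectionParams],
    s_bins: np.ndarray,
    t_bins: np.ndarray,
) -> np.ndarray:
    """Mean prediction binned by selection coefficient and onset time.

    Cell (i, j) holds the mean Pr[AI] over simulations with
    ``s_bins[i] <= s < s_bins[i+1]`` and
    ``t_bins[j] <= T_sel < t_bins[j+1]``; empty cells are NaN.
    """
    p = np.asarray(probs, dtype=float)
    if len(p) != len(params):
        raise ValueError("every probability needs matching parameters")
    s = np.asarray([q.s for q in params])
    t = np.asarray([q.T_sel for q in params])
    ns, nt = len(s_bins) - 1, len(t_bins) - 1
    grid = np.full((ns, nt), np.nan)
    si = np.digitize(s, s_bins) - 1
    ti = np.digitize(t, t_bins) - 1
    for i in range(ns):
        for j in range(nt):
            sel = (si == i) & (ti == j)
            if sel.any():
                grid[i, j] = p[sel].mean()
    return grid
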