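"""Map raw classifier scores to calibrated probabilities.

Simulated training data has even scenario ratios, but real genomes are
overwhelmingly not-AI, so raw Pr[AI] is miscalibrated in application.
The training set is first resampled to a user-chosen neutral:sweep:AI
ratio, then a calibrator is fitted to predict the true class from the
raw score.  Beta calibration is the default; isotonic regression and
Platt scaling are available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression

EPS = 1e-6

SCENARIO_CLASSES = ("neutral", "sweep", "ai")


@dataclass(frozen=True)
class ClassRatios:
    """Relative neutral:sweep:AI weights used for resampling."""

    neutral: float = 1.0
    sweep: float = 0.1
    ai: float = 0.02

    def __post_init__(self):
        w = (self.neutral, self.sweep, self.ai)
        if any(x < 0 for x in w) or all(x == 0 for x in w):
            raise ValueError("ratios must be non-negative with at least one positive")

    @classmethod
    def parse(cls, text: str) -> "ClassRatios":
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"expected 'neutral:sweep:AI', got {text!r}")
        return cls(*(float(p) for p in parts))

    def as_dict(self) -> dict[str, float]:
        return {"neutral": self.neutral, "sweep": self.sweep, "ai": self.ai}


def resample_class_ratios(
    scenarios: np.ndarray,
    ratios: ClassRatios,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices resampling a dataset to the requested class ratios.

    The class with the largest implied count is kept whole; smaller
    classes are subsampled without replacement, and classes that must
    grow are drawn with replacement.  ``scenarios`` holds per-item
    scenario labels ("neutral"/"sweep"/"ai"; "dfe" counts as neutral).
    """
    scen = np.asarray(scenarios)
    scen = np.where(scen == "dfe", "neutral", scen)
    weights = ratios.as_dict()
    idx_by_class = {}
    for cls, w in weights.items():
        idx = np.flatnonzero(scen == cls)
        if w > 0 and idx.size == 0:
            raise ValueError(f"requested class {cls!r} absent from dataset")
        idx_by_class[cls] = idx
    # choose the scale so the binding class keeps all of its items
    scale = min(
        idx_by_class[cls].size / w for cls, w in weights.items() if w > 0
    )
    out = []
    for cls, w in weights.items():
        if w == 0:
            continue
        target = max(int(round(scale * w)), 1)
        idx = idx_by_class[cls]
        if target <= idx.size:
            out.append(rng.choice(idx, size=target, replace=False))
        else:
            out.append(rng.choice(idx, size=target, replace=True))
    return np.sort(np.concatenate(out))


@dataclass
class Calibrator:
    """A fitted monotone map from raw Pr[AI] to calibrated probability.

    ``method`` is one of "beta", "isotonic", "platt".  Beta fits the
    three-parameter family  p -> 1 / (1 + exp(-c) * (1-p)^b / p^a)
    by maximum likelihood on the transformed features
    (log p, -log(1-p)); monotonicity requires a, b >= 0, and a feature
    whose coefficient comes out negative is refitted pinned to zero.
    """

    method: str = "beta"
    params: dict = field(default_factory=dict)
    fit_ratios: ClassRatios | None = None
    _iso: IsotonicRegression | None = None

    def __call__(self, raw: np.ndarray) -> np.ndarray:
        p = np.clip(np.asarray(raw, dtype=float), EPS, 1 - EPS)
        if self.method == "beta":
            a, b, c = self.params["a"], self.params["b"], self.params["c"]
            z = c + a * np.log(p) - b * np.log1p(-p)
            return 1.0 / (1.0 + np.exp(-z))
        if self.method == "platt":
            a, c = self.params["a"], self.params["c"]
            return 1.0 / (1.0 + np.exp(-(a * p + c)))
        if self.method == "isotonic":
            return np.clip(self._iso.predict(p), 0.0, 1.0)
        raise ValueError(f"unknown method {self.method!r}")

    def to_dict(self) -> dict:
        d = {"method": self.method, "params": self.params}
        if self.fit_ratios is not None:
            d["fit_ratios"] = self.fit_ratios.as_dict()
        if self.method == "isotonic":
            d["iso_x"] = list(map(float, self._iso.X_thresholds_))
            d["iso_y"] = list(map(float, self._iso.y_thresholds_))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Calibrator":
        ratios = None
        if "fit_ratios" in d:
            r = d["fit_ratios"]
            ratios = ClassRatios(r["neutral"], r["sweep"], r["ai"])
        cal = cls(d["method"], dict(d.get("params", {})), ratios)
        if d["method"] == "isotonic":
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
            iso.fit(np.asarray(d["iso_x"]), np.asarray(d["iso_y"]))
            cal._iso = iso
        return cal


def fit_calibrator(
    method: str,
    raw_scores: np.ndarray,
    labels: np.ndarray,
    fit_ratios: ClassRatios | None = None,
) -> Calibrator:
    """Fit a calibrator to binary labels (AI=1) from raw scores in [0,1]."""
    raw = np.clip(np.asarray(raw_scores, dtype=float), EPS, 1 - EPS)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class); cannot calibrate")
    if method == "beta":
        feats = np.column_stack([np.log(raw), -np.log1p(-raw)])
        use = [0, 1]
        while True:
            lr = LogisticRegression(C=np.inf, max_iter=1000)
            lr.fit(feats[:, use], y)
            coef = lr.coef_.ravel()
            neg = [u for u, cf in zip(use, coef) if cf < 0]
            if not neg:
                break
            use = [u for u in use if u not in neg]
            if not use:  # both pinned: intercept-only fit
                lr = LogisticRegression(C=np.inf, max_iter=1000)
                lr.fit(np.zeros((len(y), 1)), y)
                coef = np.zeros(0)
                break
        full = dict.fromkeys((0, 1), 0.0)
        for u, cf in zip(use, coef):
            full[u] = float(cf)
        params = {"a": full[0], "b": full[1], "c": float(lr.intercept_[0])}
        return Calibrator("beta", params, fit_ratios)
    if method == "platt":
        lr = LogisticRegression(C=np.inf, max_iter=1000)
        lr.fit(raw[:, None], y)
        params = {"a": float(lr.coef_[0, 0]), "c": float(lr.intercept_[0])}
        return Calibrator("platt", params, fit_ratios)
    if method == "isotonic":
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(raw, y)
        return Calibrator("isotonic", {}, fit_ratios, _iso=iso)
    raise ValueError(f"unknown calibration method {method!r}")


def reliability_table(
    calibrated: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 10,
) -> dict:
    """Per-bin reliability summary plus a residual-normality diagnostic.

    Bins partition [0, 1] evenly.  Returns mean prediction, empirical
    positive frequency and count per bin (empty bins have count 0 and
    NaN summaries), per-bin residuals (frequency - mean prediction) and
    a D'Agostino-Pearson normality statistic of the residuals.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = np.asarray(calibrated, dtype=float)
    y = np.asarray(labels).astype(float)
    edges = np.linspace(0, 1, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    mean_pred = np.full(n_bins, np.nan)
    freq = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        count[b] = int(sel.sum())
        if count[b]:
            mean_pred[b] = p[sel].mean()
            freq[b] = y[sel].mean()
    residuals = freq - mean_pred
    occupied = residuals[~np.isnan(residuals)]
    if occupied.size >= 8:
        stat, pval = stats.normaltest(occupied)
    else:
        stat, pval = np.nan, np.nan
    return {
        "bin_edges": edges,
        "mean_prediction": mean_pred,
        "frequency": freq,
        "count": count,
        "residuals": residuals,
        "normality_stat": float(stat) if stat == stat else np.nan,
        "normality_p": float(pval) if pval == pval else np.nan,
    }
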