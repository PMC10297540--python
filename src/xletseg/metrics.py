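"""Segmentation evaluation metrics and the Tversky index/loss.

All quantities derive from the pixel confusion counts of a predicted binary
mask against the truth mask:

* Dice  ``2|A∩B| / (|A|+|B|)`` — the F1 score of the positive class;
* Jaccard  ``|A∩B| / |A∪B|``, related to Dice by ``J = D / (2 - D)``;
* sensitivity  ``TP/P × 100`` and false-positive ratio ``FP/N × 100``;
* Tversky index  ``TP / (TP + α·FN + β·FP)`` — an asymmetric overlap that
  reduces to Dice at α = β = ½; its soft (probability-weighted) complement
  is the training loss, with α > β penalizing missed cyst pixels more than
  false alarms, the right asymmetry for rare-foreground masks.

Empty-mask conventions: both masks empty → overlap metrics are 1;
a truth mask with no positives (or no negatives) makes Sen (or FPR)
undefined and raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _as_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be strictly binary")
    return arr.astype(bool)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise TP/FP/FN/TN tallies; P and N are the truth totals."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.FP + self.TN

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class TverskyParams:
    """Tversky weights: alpha scales FN, beta scales FP; epsilon smooths the
    soft (loss) variant.  Defaults follow the training configuration
    alpha=0.8, beta=0.2."""

    alpha: float = 0.8
    beta: float = 0.2
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValueError("need alpha, beta >= 0 with alpha + beta > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError("masks must have the same shape")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    c = confusion_counts(pred, truth)
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:  # both masks empty
        return 1.0
    return 2.0 * c.TP / denom


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    c = confusion_counts(pred, truth)
    union = c.TP + c.FP + c.FN
    if union == 0:
        return 1.0
    return c.TP / union


def sensitivity_fpr(counts: ConfusionCounts) -> tuple[float, float]:
    """(Sen%, FPR%) percentages.  Raises if P or N is zero."""
    if counts.P == 0:
        raise ZeroDivisionError("sensitivity undefined: truth has no positives")
    if counts.N == 0:
        raise ZeroDivisionError("FPR undefined: truth has no negatives")
    return 100.0 * counts.TP / counts.P, 100.0 * counts.FP / counts.N


def tversky_index(counts: ConfusionCounts, params: TverskyParams) -> float:
    """``TP / (TP + alpha*FN + beta*FP)`` on integer counts (no smoothing
    needed; the degenerate 0/0 case is 1 by the empty-mask convention)."""
    denom = counts.TP + params.alpha * counts.FN + params.beta * counts.FP
    if denom == 0:
        return 1.0
    return counts.TP / denom


def soft_tversky_index(
    pred_probs: np.ndarray, truth: np.ndarray, params: TverskyParams
) -> float:
    """Probability-weighted Tversky index with epsilon smoothing:
    soft TP = sum(p*t), soft FN = sum((1-p)*t), soft FP = sum(p*(1-t))."""
    p = np.asarray(pred_probs, dtype=np.float64)
    t = _as_binary(truth).astype(np.float64)
    if p.shape != t.shape:
        raise ValueError("shapes must match")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    tp = float(np.sum(p * t))
    fn = float(np.sum((1.0 - p) * t))
    fp = float(np.sum(p * (1.0 - t)))
    denom = tp + params.alpha * fn + params.beta * fp + params.epsilon
    if denom == 0:
        return 1.0
    return (tp + params.epsilon) / denom


def tversky_loss(
    pred_probs: np.ndarray, truth: np.ndarray, params: TverskyParams
) -> float:
    """``1 - soft Tversky index`` — the training loss."""
    return 1.0 - soft_tversky_index(pred_probs, truth, params)


# ---------------------------------------------------------------------------
# per-image report
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ("dice", "jaccard", "sen_pct", "fpr_pct")


@dataclass
class MetricsReport:
    """Per-image metric rows plus mean/median aggregates."""

    per_image: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path) -> None:
        self.per_image.to_csv(path, index=False, float_format="%.6f")


def image_row(image_id: str, pred: np.ndarray, truth: np.ndarray) -> dict:
    """Compute one report row for a (prediction, truth) mask pair."""
    c = confusion_counts(pred, truth)
    sen, fpr = sensitivity_fpr(c)
    return {
        "image_id": image_id,
        "dice": dice(pred, truth),
        "jaccard": jaccard(pred, truth),
        "sen_pct": sen,
        "fpr_pct": fpr,
    }


def aggregate_report(rows: list[dict]) -> MetricsReport:
    """Assemble per-image rows (stable order) and mean/median summaries."""
    if not rows:
        raise ValueError("no rows to aggregate")
    per_image = pd.DataFrame(rows, columns=["image_id", *METRIC_COLUMNS])
    summary = pd.DataFrame(
        {
            "statistic": ["mean", "median"],
            **{
                col: [per_image[col].mean(), per_image[col].median()]
                for col in METRIC_COLUMNS
            },
        }
    )
    return MetricsReport(per_image=per_image, summary=summary)
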