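"""Metrics and model-comparison statistics.

Predictions are binarized at 0.5 (ties count as foreground) for the
confusion-matrix metrics; the Dice coefficient and the losses are computed
on the raw (soft) probabilities. Metrics are pooled over all pixels of the
evaluation set (micro aggregation) by default, matching single-number
reports over a whole test set; macro (per-image mean) aggregation is
available for comparison.

Pairs of models are compared with McNemar's test on pixel-wise correctness
over the whole test set: discordant counts b (A correct, B wrong) and c
(B correct, A wrong) feed the chi-square statistic with one degree of
freedom, with Yates' continuity correction on by default, and significance
is assessed at a Bonferroni-adjusted level alpha / m.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .components import LossConfig, bce_dice_loss, bce_loss, dice_coefficient

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "accuracy", "loss", "dice_loss", "precision", "f1",
    "sensitivity", "specificity", "dice_coefficient",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The eight-column metric report for one model on one evaluation set."""

    accuracy: float
    loss: float
    dice_loss: float
    precision: float
    f1: float
    sensitivity: float
    specificity: float
    dice_coefficient: float

    def to_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in METRIC_COLUMNS}

    def to_frame(self, name: str = "model") -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()], index=[name])


@dataclass(frozen=True)
class McNemarResult:
    b: int  # pixels where A is correct and B is wrong
    c: int  # pixels where B is correct and A is wrong
    statistic: float
    p_value: float
    significant_raw: bool = False
    significant_bonferroni: bool = False


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities into a {0, 1} mask; p >= threshold maps to 1."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    prob = np.asarray(prob)
    return (prob >= threshold).astype(np.uint8)


def confusion_counts(truth: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Pooled pixel confusion counts over arbitrarily shaped mask stacks."""
    t = np.asarray(truth).astype(bool)
    p = np.asarray(pred).astype(bool)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {t.shape} vs pred {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); reporting 0", name)
        return 0.0
    return num / den


def compute_metrics(
    counts: ConfusionCounts,
    loss: float,
    dice: float,
) -> MetricsReport:
    """Assemble the report from thresholded counts plus the soft quantities.

    accuracy/precision/sensitivity/specificity/F1 come from the counts;
    ``dice`` is the soft Dice coefficient and ``loss`` the BCEDice loss on
    the un-thresholded probabilities.
    """
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    return MetricsReport(
        accuracy=_ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        loss=loss,
        dice_loss=1.0 - dice,
        precision=precision,
        f1=_ratio(2 * precision * sensitivity, precision + sensitivity, "f1"),
        sensitivity=sensitivity,
        specificity=_ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        dice_coefficient=dice,
    )


def evaluate_predictions(
    truth: np.ndarray,
    prob: np.ndarray,
    loss_cfg: LossConfig = LossConfig(),
    threshold: float = 0.5,
    per_image: bool = False,
) -> MetricsReport:
    """Full metric report for probability maps against binary truth.

    With ``per_image`` the report is the unweighted mean of per-image
    reports (macro); otherwise all pixels are pooled (micro).
    """
    truth = np.asarray(truth, dtype=float)
    prob = np.asarray(prob, dtype=float)
    if truth.shape != prob.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape} vs prob {prob.shape}")
    if per_image:
        reports = [
            evaluate_predictions(t, p, loss_cfg, threshold, per_image=False)
            for t, p in zip(truth, prob)
        ]
        return MetricsReport(
            **{
                c: float(np.mean([getattr(r, c) for r in reports]))
                for c in METRIC_COLUMNS
            }
        )
    counts = confusion_counts(truth, binarize(prob, threshold))
    return compute_metrics(
        counts,
        loss=bce_dice_loss(truth, prob, loss_cfg),
        dice=dice_coefficient(truth, prob, loss_cfg),
    )


# ----------------------------------------------------------------------
# McNemar pairwise comparison
# ----------------------------------------------------------------------

def mcnemar_pixelwise(
    truth: np.ndarray,
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    continuity_correction: bool = True,
) -> McNemarResult:
    """McNemar's chi-square test (1 df) on pixel-wise correctness.

    b counts pixels where only model A agrees with the truth, c where only
    model B does. The corrected statistic is (|b - c| - 1)^2 / (b + c)
    (clamped to 0 when |b - c| <= 1 or b + c = 0); the p-value is the
    chi-square(1) upper-tail probability.
    """
    t = np.asarray(truth).astype(bool)
    a = np.asarray(pred_a).astype(bool)
    bm = np.asarray(pred_b).astype(bool)
    if not (t.shape == a.shape == bm.shape):
        raise ValueError(
            f"shape mismatch: truth {t.shape}, A {a.shape}, B {bm.shape}"
        )
    correct_a = a == t
    correct_b = bm == t
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if b + c == 0:
        stat = 0.0
    elif continuity_correction:
        diff = max(abs(b - c) - 1.0, 0.0)
        stat = diff * diff / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    p = float(chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return McNemarResult(b=b, c=c, statistic=float(stat), p_value=p)


def bonferroni_threshold(alpha: float = 0.1, m_comparisons: int = 1) -> float:
    """Adjusted per-comparison significance level alpha / m."""
    if m_comparisons < 1:
        raise ValueError(f"m_comparisons must be >= 1, got {m_comparisons}")
    return alpha / m_comparisons


def compare_models(
    truth: np.ndarray,
    predictions: dict[str, np.ndarray],
    alpha: float = 0.1,
    continuity_correction: bool = True,
) -> tuple[pd.DataFrame, dict[tuple[str, str], McNemarResult]]:
    """All-pairs McNemar comparison with Bonferroni-adjusted significance.

    Returns a lower-triangular p-value matrix (rows/columns in the given
    model order) and the per-pair results keyed by (row model, column model).
    """
    names = list(predictions)
    if len(names) < 2:
        raise ValueError("need at least 2 models to compare")
    pairs = list(itertools.combinations(names, 2))
    adjusted = bonferroni_threshold(alpha, len(pairs))
    matrix = pd.DataFrame(np.nan, index=names, columns=names)
    results: dict[tuple[str, str], McNemarResult] = {}
    for a_name, b_name in pairs:
        res = mcnemar_pixelwise(
            truth, predictions[a_name], predictions[b_name], continuity_correction
        )
        res = McNemarResult(
            b=res.b, c=res.c, statistic=res.statistic, p_value=res.p_value,
            significant_raw=res.p_value < alpha,
            significant_bonferroni=res.p_value < adjusted,
        )
        results[(b_name, a_name)] = res
        matrix.loc[b_name, a_name] = res.p_value  # lower triangle
    return matrix, results


def render_comparison(matrix: pd.DataFrame, adjusted_alpha: float) -> str:
    """Human-readable text table of the pairwise p-value matrix."""
    lines = [
        f"pairwise McNemar p-values (significant below {adjusted_alpha:.4g} "
        "after Bonferroni)",
        matrix.to_string(float_format=lambda v: f"{v:.4g}", na_rep=""),
    ]
    return "\n".join(lines)
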