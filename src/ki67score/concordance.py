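"""Agreement statistics, Oncotype DX risk grouping and confusion conventions.

Pearson's r measures linear association; Lin's concordance correlation
coefficient (CCC) additionally penalizes location and scale shifts, so it is
the right statistic when two methods are supposed to return the *same*
number, not merely correlated ones:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2)

with population (1/n) moments. |CCC| <= |r| always, with equality iff the
two series share mean and variance.

Risk groups follow the Genomic Health cut-points on the 0-100 Recurrence
Score: low < 18, intermediate 18-30, high >= 31. The confusion-matrix
conventions are deliberately asymmetric: a correctly predicted *low*-risk
patient is a true positive, a correctly predicted *high*-risk patient a true
negative, and intermediate-risk patients (actual or predicted) are excluded
from evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

from .errors import InvalidInputError, UndefinedStatisticError

__all__ = [
    "RISK_LOW",
    "RISK_INTERMEDIATE",
    "RISK_HIGH",
    "ConfusionSummary",
    "pearson_r",
    "lins_ccc",
    "assign_risk_group",
    "confusion_summary",
    "cohort_summary",
]

RISK_LOW = "low"
RISK_INTERMEDIATE = "intermediate"
RISK_HIGH = "high"


def _paired(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D series of equal length")
    if len(x) < min_n:
        raise InvalidInputError(f"need at least {min_n} pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidInputError("pairs must be finite")
    return x, y


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-tailed p-value (t, n-2 df)."""
    x, y = _paired(x, y)
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def lins_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population-moment form)."""
    x, y = _paired(x, y)
    sx2 = np.var(x)  # population (1/n) moments throughout
    sy2 = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise UndefinedStatisticError(
            "CCC undefined: both series constant and equal (0/0)"
        )
    return float(2.0 * sxy / denom)


def assign_risk_group(rs: float) -> str:
    """Map a Recurrence Score to its risk group.

    low: rs < 18; high: rs >= 31; everything in between (including
    non-integer scores in (30, 31)) is intermediate.
    """
    if not np.isfinite(rs) or rs < 0 or rs > 100:
        raise InvalidInputError(f"Recurrence Score must lie in [0, 100], got {rs}")
    if rs < 18:
        return RISK_LOW
    if rs >= 31:
        return RISK_HIGH
    return RISK_INTERMEDIATE


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts plus the derived percentages.

    Metrics with a zero denominator are ``None`` and listed in
    ``undefined_metrics`` rather than silently coerced to 0 or 100.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    n_excluded_intermediate: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    @property
    def undefined_metrics(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv")
            if getattr(self, name) is None
        )


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def confusion_summary(predicted: list[str], actual: list[str]) -> ConfusionSummary:
    """Tally the asymmetric low/high confusion matrix.

    TP = correctly predicted low, TN = correctly predicted high,
    FP = actual high predicted low, FN = actual low predicted high.
    Pairs where either label is intermediate are excluded and counted.
    """
    if len(predicted) != len(actual):
        raise InvalidInputError("predicted and actual must have equal length")
    valid = {RISK_LOW, RISK_INTERMEDIATE, RISK_HIGH}
    if not set(predicted) <= valid or not set(actual) <= valid:
        raise InvalidInputError("labels must be low/intermediate/high")

    tp = tn = fp = fn = excluded = 0
    for p, a in zip(predicted, actual):
        if RISK_INTERMEDIATE in (p, a):
            excluded += 1
        elif a == RISK_LOW:
            tp += p == RISK_LOW
            fn += p == RISK_HIGH
        else:  # actual high
            tn += p == RISK_HIGH
            fp += p == RISK_LOW
    total = tp + tn + fp + fn
    if total == 0:
        raise InvalidInputError("all pairs excluded: no low/high pairs to evaluate")
    return ConfusionSummary(
        tp=tp, tn=tn, fp=fp, fn=fn,
        n_excluded_intermediate=excluded,
        accuracy=_ratio(tp + tn, total),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (so 56.35 -> 56.4), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_summary(counts: dict[str, int], total: int) -> dict[str, float]:
    """Per-category percentages of a cohort characteristics table, 1 decimal."""
    if total <= 0:
        raise InvalidInputError("category total must be positive")
    if any(c < 0 for c in counts.values()):
        raise InvalidInputError("counts must be non-negative")
    return {k: round_half_away(100.0 * c / total, 1) for k, c in counts.items()}
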