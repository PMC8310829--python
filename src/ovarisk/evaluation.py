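"""Diagnostic-accuracy metrics against the histology reference standard.

Predictions are binary risk classes (very-low vs medium-high) and the
reference is binary histology (benign vs malignant); ``medium_high``
paired with ``malignant`` is the positive outcome. All interval
estimates are exact (Clopper-Pearson) binomial confidence intervals,
the only standard construction whose two-sided 95% bounds match worked
reference values such as a lower limit of 83.2% for 20/20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricWithCI",
    "clopper_pearson",
    "confusion",
    "metrics",
    "round_half_up",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally: positive = malignant reference / medium-high prediction."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricWithCI:
    """A proportion with its exact binomial 95% CI and the defining ratio."""

    point: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    @property
    def percent(self) -> float:
        """Point estimate as a percentage rounded half-up to one decimal."""
        return round_half_up(100.0 * self.point, 1)

    @property
    def ci_percent(self) -> tuple[float, float]:
        return (
            round_half_up(100.0 * self.ci_low, 1),
            round_half_up(100.0 * self.ci_high, 1),
        )

    def __str__(self) -> str:
        lo, hi = self.ci_percent
        return f"{self.numerator}/{self.denominator}, {self.percent}% ({lo}-{hi})"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (87.85 -> 87.9), unlike banker's rounding."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def clopper_pearson(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles.

    The lower bound is the Beta(x, n-x+1) quantile at alpha/2 and the upper
    the Beta(x+1, n-x) quantile at 1-alpha/2, with the conventional closed
    forms at the boundaries: x=0 gives a lower bound of exactly 0 and
    x=n an upper bound of exactly 1 (then low = (alpha/2)**(1/n)).
    """
    x, n = successes, trials
    if n < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"successes {x} outside [0, {n}]")
    alpha = 1.0 - confidence
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return low, high


def confusion(predictions, labels) -> ConfusionCounts:
    """Tally a 2x2 confusion table.

    Both arguments are equal-length sequences of booleans (or of the strings
    ``medium_high``/``very_low`` and ``malignant``/``benign``), True meaning
    positive.
    """
    pred = np.asarray([_as_positive(p) for p in predictions], dtype=bool)
    ref = np.asarray([_as_positive(y) for y in labels], dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predictions vs {ref.shape[0]} labels"
        )
    return ConfusionCounts(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        tn=int(np.sum(~pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
    )


_POSITIVE_TOKENS = {"medium_high", "malignant", "1", "true"}
_NEGATIVE_TOKENS = {"very_low", "benign", "0", "false"}


def _as_positive(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return bool(value)
    token = str(value).strip().lower()
    if token in _POSITIVE_TOKENS:
        return True
    if token in _NEGATIVE_TOKENS:
        return False
    raise ValueError(f"unrecognized binary outcome {value!r}")


def metrics(
    counts: ConfusionCounts, confidence: float = 0.95
) -> dict[str, MetricWithCI | None]:
    """Sensitivity, specificity, accuracy, PPV and NPV with exact 95% CIs.

    A metric whose denominator is zero (e.g. sensitivity with no positive
    reference cases) is returned as None; the others are still computed.
    """
    pairs = {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "accuracy": (counts.tp + counts.tn, counts.total),
        "ppv": (counts.tp, counts.tp + counts.fp),
        "npv": (counts.tn, counts.tn + counts.fn),
    }
    out: dict[str, MetricWithCI | None] = {}
    for name, (num, den) in pairs.items():
        if den == 0:
            out[name] = None
            continue
        low, high = clopper_pearson(num, den, confidence)
        out[name] = MetricWithCI(
            point=num / den, ci_low=low, ci_high=high, numerator=num, denominator=den
        )
    return out
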