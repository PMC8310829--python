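"""Rule-based integration of radiomic risk, acoustic shadow and CA-125.

The published decision flow applies three rules on top of the ultrasound-only
radiomic prediction:

1. no acoustic shadow and CA-125 below threshold -> the radiomic class stands;
2. acoustic shadow present and CA-125 below threshold -> very low risk;
3. CA-125 above threshold (shadow irrelevant) -> medium-high risk.

The CA-125 threshold is menopause-dependent: 71 U/mL after menopause (twice
the upper normal level) and 200 U/mL before. "Above" is a strict comparison;
a value exactly at the threshold is below.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "RiskClass",
    "Route",
    "DecisionThresholds",
    "RoutedDecision",
    "ca125_above",
    "integrate_risk",
    "route_counts",
]


class RiskClass(str, Enum):
    VERY_LOW = "very_low"
    MEDIUM_HIGH = "medium_high"


class Route(str, Enum):
    CA125_OVERRIDE = "ca125_override"
    SHADOW_OVERRIDE = "shadow_override"
    RADIOMIC = "radiomic"


@dataclass(frozen=True)
class DecisionThresholds:
    """Menopause-corrected CA-125 cut-offs in U/mL."""

    ca125_post: float = 71.0
    ca125_pre: float = 200.0

    def __post_init__(self) -> None:
        if self.ca125_post <= 0 or self.ca125_pre <= 0:
            raise ValueError("CA-125 thresholds must be positive")

    def for_status(self, menopausal: str) -> float:
        if menopausal == "post":
            return self.ca125_post
        if menopausal == "pre":
            return self.ca125_pre
        raise ValueError(f"menopausal status must be 'pre' or 'post', got {menopausal!r}")


@dataclass(frozen=True)
class RoutedDecision:
    """Final risk class, the rule that produced it, and the audited inputs."""

    final: RiskClass
    route: Route
    radiomic: Optional[RiskClass] = None
    shadow_present: Optional[bool] = None
    ca125_above_threshold: Optional[bool] = None
    extra: dict = field(default_factory=dict, compare=False)


def ca125_above(
    ca125: float,
    menopausal: str,
    thresholds: DecisionThresholds | None = None,
) -> bool:
    """Strictly compare a serum CA-125 level with its menopause-specific cut-off."""
    if ca125 < 0 or ca125 != ca125:
        raise ValueError(f"CA-125 must be a finite non-negative level, got {ca125!r}")
    thresholds = thresholds or DecisionThresholds()
    return ca125 > thresholds.for_status(menopausal)


def integrate_risk(
    radiomic: Optional[RiskClass],
    shadow_present: bool,
    above: bool,
) -> RoutedDecision:
    """Apply the three decision rules; CA-125 dominates the shadow rule.

    ``radiomic`` may be None on the override routes (it is echoed for audit
    when given) but is mandatory when neither override applies.
    """
    if radiomic is not None:
        radiomic = RiskClass(radiomic)
    if above:
        final, route = RiskClass.MEDIUM_HIGH, Route.CA125_OVERRIDE
    elif shadow_present:
        final, route = RiskClass.VERY_LOW, Route.SHADOW_OVERRIDE
    else:
        if radiomic is None:
            raise ValueError(
                "radiomic prediction required: no shadow and CA-125 below threshold"
            )
        final, route = radiomic, Route.RADIOMIC
    return RoutedDecision(
        final=final,
        route=route,
        radiomic=radiomic,
        shadow_present=bool(shadow_present),
        ca125_above_threshold=bool(above),
    )


def route_counts(decisions: Iterable[RoutedDecision]) -> dict[str, dict[str, float]]:
    """Tally decisions per route with integer-rounded percentages of the total."""
    tally = Counter(d.route for d in decisions)
    total = sum(tally.values())
    out: dict[str, dict[str, float]] = {}
    for route in Route:
        n = tally.get(route, 0)
        pct = round(100.0 * n / total) if total else 0
        out[route.value] = {"count": n, "percent": pct}
    out["total"] = {"count": total, "percent": 100 if total else 0}
    return out
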