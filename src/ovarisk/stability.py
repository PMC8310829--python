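"""Feature robustness to contour manipulation, scored by ICC(1,1).

Each mass is segmented many times (the random contour variants); a feature
is worth keeping only if its variation across variants of the same mass is
small relative to its variation across masses. That is a one-way
intraclass correlation, ICC(1,1), with masses as subjects and the contour
variants as interchangeable raters:

    ICC = (MS_between - MS_within) / (MS_between + (k - 1) * MS_within)

clipped to [0, 1]. Features with no variance at all (degenerate) are
flagged and excluded from selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ICC_THRESHOLD = 0.75

__all__ = [
    "StabilityReport",
    "FeatureStability",
    "icc_oneway",
    "feature_stability",
    "select_panel",
]


@dataclass(frozen=True)
class FeatureStability:
    name: str
    icc: float  # NaN when degenerate
    degenerate: bool
    selected: bool


@dataclass
class StabilityReport:
    per_feature: dict[str, FeatureStability]
    threshold: float

    def selected_names(self) -> list[str]:
        """Selected features, ordered by descending ICC with name tie-break."""
        chosen = [f for f in self.per_feature.values() if f.selected]
        return [f.name for f in sorted(chosen, key=lambda f: (-f.icc, f.name))]


def icc_oneway(table: np.ndarray) -> float:
    """ICC(1,1) from a subjects x repeats table (NaN = missing repeat).

    Ragged designs are handled with the harmonic-mean number of repeats.
    Returns NaN for degenerate input (zero total variance).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need >= 2 subjects in a 2D table")
    counts = np.sum(~np.isnan(table), axis=1)
    if np.any(counts < 2):
        raise ValueError("every subject needs >= 2 repeats")
    n = table.shape[0]
    if not np.all(counts == counts[0]):
        logger.warning("ragged variant counts; using harmonic-mean k")
    k = n / np.sum(1.0 / counts)

    subj_means = np.nanmean(table, axis=1)
    grand = np.nansum(table) / np.sum(counts)
    total_var = np.nanvar(table)
    if total_var < 1e-24 * max(1.0, grand**2):
        return float("nan")
    ss_within = np.nansum((table - subj_means[:, None]) ** 2)
    ms_within = ss_within / np.sum(counts - 1)
    ss_between = np.sum(counts * (subj_means - grand) ** 2)
    ms_between = ss_between / (n - 1)
    icc = (ms_between - ms_within) / (ms_between + (k - 1.0) * ms_within)
    return float(np.clip(icc, 0.0, 1.0))


def feature_stability(
    feature_matrix: pd.DataFrame,
    threshold: float = DEFAULT_ICC_THRESHOLD,
) -> StabilityReport:
    """Score every feature column of a (mass, variant)-indexed table.

    ``feature_matrix`` must have a MultiIndex (case_id, variant) or columns
    ``case_id``/``variant`` plus one column per feature.
    """
    df = feature_matrix
    if not isinstance(df.index, pd.MultiIndex):
        if {"case_id", "variant"}.issubset(df.columns):
            df = df.set_index(["case_id", "variant"])
        else:
            raise ValueError("expected (case_id, variant) MultiIndex or columns")
    cases = df.index.get_level_values(0)
    if cases.nunique() < 2:
        raise ValueError("need >= 2 masses for stability analysis")

    per_feature: dict[str, FeatureStability] = {}
    for name in sorted(df.columns):
        wide = df[name].unstack()  # cases x variants, NaN where missing
        icc = icc_oneway(wide.to_numpy())
        degenerate = bool(np.isnan(icc))
        selected = (not degenerate) and icc >= threshold
        per_feature[name] = FeatureStability(
            name=name, icc=icc, degenerate=degenerate, selected=selected
        )
    return StabilityReport(per_feature=per_feature, threshold=threshold)


def select_panel(
    report: StabilityReport,
    mass_type: str,
    threshold: float | None = None,
) -> list[str]:
    """Deterministic stable-feature panel for one mass type.

    Re-applies the threshold if one is given; raises if nothing survives.
    """
    if threshold is not None and threshold != report.threshold:
        chosen = [
            f.name
            for f in report.per_feature.values()
            if not f.degenerate and f.icc >= threshold
        ]
        ordered = sorted(chosen, key=lambda nm: (-report.per_feature[nm].icc, nm))
    else:
        ordered = report.selected_names()
    if not ordered:
        raise ValueError(
            f"no stable features for {mass_type!r} at threshold "
            f"{threshold if threshold is not None else report.threshold}; "
            "lower the threshold"
        )
    return ordered
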