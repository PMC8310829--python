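"""End-to-end orchestration: perturb, extract, select, train, predict, evaluate.

This module wires the stages together the way the stand-alone tool uses
them: every mass contour is randomly manipulated into ``n_variants``
plausible tracings, radiomic features are extracted per variant, feature
panels are selected for stability across variants, one classifier per
mass type is trained on median-aggregated features, and final risk is
obtained by routing the radiomic prediction through the shadow and
CA-125 rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .decision import (
    DecisionThresholds,
    RoutedDecision,
    ca125_above,
    integrate_risk,
)
from .io import ClinicalRecord, Frame, MassAnnotation, read_frame, read_manifest
from .models import (
    ModelConfig,
    TrainedEnsemble,
    aggregate_variants,
    predict_radiomic,
    train_ensemble,
)
from .phantom import PhantomCase
from .radiomics import DiscretizationConfig, extract_all
from .segmentation import PerturbationConfig, rasterize
from .stability import DEFAULT_ICC_THRESHOLD, feature_stability, select_panel

__all__ = [
    "PipelineConfig",
    "load_cases",
    "extract_case_features",
    "extract_cohort_features",
    "build_panels",
    "fit_dss",
    "predict_case",
    "predict_cohort",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Effective settings of one run; serialized alongside every output."""

    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    icc_threshold: float = DEFAULT_ICC_THRESHOLD
    model: ModelConfig = field(default_factory=ModelConfig)
    thresholds: DecisionThresholds = field(default_factory=DecisionThresholds)

    def to_dict(self) -> dict:
        return {
            "perturbation": self.perturbation.__dict__,
            "discretization": {
                "n_bins": self.discretization.n_bins,
                "range_mode": self.discretization.range_mode,
                "fixed_range": self.discretization.fixed_range,
            },
            "icc_threshold": self.icc_threshold,
            "model": self.model.__dict__,
            "thresholds": self.thresholds.__dict__,
        }


def load_cases(manifest_path: str | Path) -> list[PhantomCase]:
    """Load a cohort (frames, annotations, clinical data) from a manifest."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    cases = []
    for r in read_manifest(manifest_path):
        frame = read_frame(base / r.image_path, case_id=r.case_id)
        cases.append(
            PhantomCase(
                frame=frame,
                annotation=r.annotation,
                clinical=r.clinical,
                label=r.label,
                case_id=r.case_id,
            )
        )
    return cases


def _case_seed(base_seed: int, case_id: str) -> int:
    """Stable per-case perturbation seed (independent of cohort order)."""
    h = 2166136261
    for ch in f"{base_seed}:{case_id}".encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return int(h % (2**31))


def extract_case_features(
    frame: Frame,
    annotation: MassAnnotation,
    cfg: PipelineConfig,
    case_id: str,
    label: str | None = None,
) -> pd.DataFrame:
    """Per-variant feature rows for one mass (variant 0 .. n_variants-1)."""
    from .segmentation import perturb_contour

    pert = PerturbationConfig(
        n_variants=cfg.perturbation.n_variants,
        amplitude_frac=cfg.perturbation.amplitude_frac,
        smoothness=cfg.perturbation.smoothness,
        seed=_case_seed(cfg.perturbation.seed, case_id),
    )
    variants = perturb_contour(annotation.contour, pert, frame.shape)
    rows = []
    for v_idx, contour in enumerate(variants):
        mask = rasterize(contour, frame.shape)
        fv = extract_all(
            frame,
            mask,
            annotation.mass_type,
            disc_cfg=cfg.discretization,
            provenance=(case_id, v_idx),
        )
        row = {"case_id": case_id, "variant": v_idx, "mass_type": annotation.mass_type}
        if label is not None:
            row["label"] = label
        row.update(fv.values)
        rows.append(row)
    return pd.DataFrame(rows)


def extract_cohort_features(
    cases: list[PhantomCase], cfg: PipelineConfig
) -> pd.DataFrame:
    """Long feature table (one row per case x variant) for a phantom cohort."""
    frames = [
        extract_case_features(
            c.frame, c.annotation, cfg, case_id=c.case_id, label=c.label
        )
        for c in cases
    ]
    return pd.concat(frames, ignore_index=True)


def stability_reports(
    long_features: pd.DataFrame, cfg: PipelineConfig
) -> dict[str, "StabilityReport"]:
    """Per-mass-type stability reports from a long (case x variant) table."""
    from .stability import StabilityReport  # noqa: F401 - typing aid

    reports = {}
    for mass_type, group in long_features.groupby("mass_type"):
        feature_cols = [
            c
            for c in group.columns
            if c not in ("case_id", "variant", "mass_type", "label")
        ]
        # solid-subregion features exist only for mixed masses
        cols = [c for c in feature_cols if group[c].notna().all()]
        table = group[["case_id", "variant"] + cols]
        reports[str(mass_type)] = feature_stability(table, threshold=cfg.icc_threshold)
    return reports


def build_panels(
    long_features: pd.DataFrame, cfg: PipelineConfig
) -> dict[str, list[str]]:
    """Stability-select one feature panel per mass type from training data."""
    return {
        mass_type: select_panel(report, mass_type)
        for mass_type, report in stability_reports(long_features, cfg).items()
    }


def fit_dss(
    train_cases: list[PhantomCase], cfg: PipelineConfig | None = None
) -> tuple[TrainedEnsemble, dict[str, list[str]], pd.DataFrame]:
    """Full training pass: features -> panels -> ensemble.

    Returns the fitted ensemble, the per-type panels and the long feature
    table (useful for audit and reuse).
    """
    cfg = cfg or PipelineConfig()
    long_features = extract_cohort_features(train_cases, cfg)
    panels = build_panels(long_features, cfg)
    per_case = aggregate_variants(long_features)
    ensemble = train_ensemble(per_case, panels, cfg.model)
    return ensemble, panels, long_features


def predict_case(
    ensemble: TrainedEnsemble,
    frame: Frame,
    annotation: MassAnnotation,
    clinical: ClinicalRecord,
    cfg: PipelineConfig,
    case_id: str = "",
) -> RoutedDecision:
    """DSS decision for one mass.

    The radiomic model is always evaluated (median-aggregated over contour
    variants) and echoed for audit, even when an override rule decides.
    """
    long_features = extract_case_features(frame, annotation, cfg, case_id or "case")
    per_case = aggregate_variants(long_features)
    mapping = per_case.iloc[0].to_dict()
    radiomic, score = predict_radiomic(ensemble, mapping, annotation.mass_type)
    above = ca125_above(clinical.ca125, clinical.menopausal, cfg.thresholds)
    decision = integrate_risk(radiomic, annotation.shadow_present, above)
    decision.extra["score"] = score
    decision.extra["case_id"] = case_id
    return decision


def predict_cohort(
    ensemble: TrainedEnsemble,
    cases: list[PhantomCase],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """One audited decision row per case."""
    rows = []
    for c in cases:
        d = predict_case(ensemble, c.frame, c.annotation, c.clinical, cfg, c.case_id)
        rows.append(
            {
                "case_id": c.case_id,
                "mass_type": c.annotation.mass_type,
                "shadow": int(c.annotation.shadow_present),
                "ca125": c.clinical.ca125,
                "menopausal": c.clinical.menopausal,
                "radiomic_risk": d.radiomic.value,
                "score": d.extra["score"],
                "route": d.route.value,
                "final_risk": d.final.value,
                "label": c.label,
            }
        )
    return pd.DataFrame(rows)
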