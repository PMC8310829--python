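"""The ensemble of three radiomic risk classifiers, one per mass echotexture.

Each mass type (solid / cystic / mixed) gets its own binary classifier,
fit on that type's stable feature panel after z-score standardization.
The default classifier is a linear support-vector machine (C = 1), the
usual choice for small-n tabular radiomics; logistic regression and a
random forest are available alternatives. The continuous decision score
is thresholded at an operating point chosen to maximize sensitivity
subject to a specificity floor, and performance is reported by stratified
k-fold cross-validation with fold-wise threshold selection (no test-fold
leakage).

At inference the per-variant feature vectors of a mass are aggregated by
the median across the random contour manipulations before scoring, which
is what makes the prediction robust to the operator's exact tracing.
"""

from __future__ import annotations

import base64
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .decision import RiskClass
from .radiomics import FeatureVector

MASS_TYPES = ("solid", "cystic", "mixed")
FORMAT_VERSION = 1

__all__ = [
    "ModelConfig",
    "TypeModel",
    "TrainedEnsemble",
    "train_ensemble",
    "predict_radiomic",
    "aggregate_variants",
    "choose_threshold",
]


@dataclass(frozen=True)
class ModelConfig:
    classifier: str = "linear_svm"  # linear_svm | logistic | random_forest
    C: float = 1.0
    n_folds: int = 10
    specificity_floor: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in ("linear_svm", "logistic", "random_forest"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if not 0.0 <= self.specificity_floor < 1.0:
            raise ValueError("specificity_floor must lie in [0, 1)")


def _make_classifier(cfg: ModelConfig):
    if cfg.classifier == "linear_svm":
        return SVC(kernel="linear", C=cfg.C, random_state=cfg.seed)
    if cfg.classifier == "logistic":
        return LogisticRegression(C=cfg.C, max_iter=5000, random_state=cfg.seed)
    return RandomForestClassifier(n_estimators=200, random_state=cfg.seed)


@dataclass
class TypeModel:
    """Fitted scaler + classifier + operating threshold for one mass type."""

    mass_type: str
    panel: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    kind: str
    threshold: float
    coef: np.ndarray | None = None  # linear families
    intercept: float | None = None
    blob: bytes | None = None  # pickled estimator for non-linear families

    def score(self, x: np.ndarray) -> float:
        """Continuous malignancy score for one standardized panel vector."""
        z = (x - self.scaler_mean) / self.scaler_scale
        if self.kind in ("linear_svm", "logistic"):
            return float(z @ self.coef + self.intercept)
        est = pickle.loads(self.blob)
        return float(est.predict_proba(z[None, :])[0, 1])


@dataclass
class TrainedEnsemble:
    models: dict[str, TypeModel]
    config: ModelConfig
    cv_report: pd.DataFrame
    version: int = FORMAT_VERSION

    # -- serialization (JSON; exact float round-trip via repr) --------------
    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config": self.config.__dict__,
            "cv_report": self.cv_report.to_dict(orient="list"),
            "models": {},
        }
        for t, m in self.models.items():
            payload["models"][t] = {
                "mass_type": m.mass_type,
                "panel": m.panel,
                "scaler_mean": m.scaler_mean.tolist(),
                "scaler_scale": m.scaler_scale.tolist(),
                "kind": m.kind,
                "threshold": m.threshold,
                "coef": None if m.coef is None else m.coef.tolist(),
                "intercept": m.intercept,
                "blob": None if m.blob is None else base64.b64encode(m.blob).decode(),
            }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrainedEnsemble":
        payload = json.loads(text)
        models = {}
        for t, d in payload["models"].items():
            models[t] = TypeModel(
                mass_type=d["mass_type"],
                panel=list(d["panel"]),
                scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
                scaler_scale=np.asarray(d["scaler_scale"], dtype=float),
                kind=d["kind"],
                threshold=float(d["threshold"]),
                coef=None if d["coef"] is None else np.asarray(d["coef"], dtype=float),
                intercept=d["intercept"],
                blob=None if d["blob"] is None else base64.b64decode(d["blob"]),
            )
        return cls(
            models=models,
            config=ModelConfig(**payload["config"]),
            cv_report=pd.DataFrame(payload["cv_report"]),
            version=payload["version"],
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEnsemble":
        return cls.from_json(Path(path).read_text())


def choose_threshold(
    scores: np.ndarray, y: np.ndarray, specificity_floor: float
) -> float:
    """Operating point maximizing sensitivity s.t. specificity >= floor.

    Candidates are midpoints between adjacent sorted scores (plus outer
    sentinels). If no candidate reaches the floor, the most specific one is
    returned.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=bool)
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best = None  # (sens, spec, threshold)
    fallback = None
    n_pos, n_neg = y.sum(), (~y).sum()
    for thr in candidates:
        pred = scores > thr
        sens = np.sum(pred & y) / n_pos if n_pos else 1.0
        spec = np.sum(~pred & ~y) / n_neg if n_neg else 1.0
        if fallback is None or spec > fallback[1]:
            fallback = (sens, spec, thr)
        if spec >= specificity_floor:
            if best is None or (sens, spec) > (best[0], best[1]):
                best = (sens, spec, thr)
    return float((best or fallback)[2])


def _fit_one(
    X: np.ndarray, y: np.ndarray, cfg: ModelConfig
) -> tuple[np.ndarray, np.ndarray, object]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    clf = _make_classifier(cfg)
    clf.fit((X - mean) / scale, y.astype(int))
    return mean, scale, clf

def _scores(clf, Xz: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    if cfg.classifier == "random_forest":
        return clf.predict_proba(Xz)[:, 1]
    return clf.decision_function(Xz)


def train_ensemble(
    features: pd.DataFrame,
    panels: Mapping[str, list[str]],
    cfg: ModelConfig | None = None,
) -> TrainedEnsemble:
    """Fit the three per-type models and report cross-validated performance.

    ``features`` holds one row per mass (variant-aggregated) with columns
    ``case_id``, ``mass_type``, ``label`` plus the feature columns; ``panels``
    maps each mass type to its stable feature panel.
    """
    cfg = cfg or ModelConfig()
    models: dict[str, TypeModel] = {}
    rows = []
    pooled_pred: list[np.ndarray] = []
    pooled_true: list[np.ndarray] = []
    for mass_type in MASS_TYPES:
        stratum = features[features["mass_type"] == mass_type]
        if stratum.empty:
            raise ValueError(f"no training cases for mass type {mass_type!r}")
        y = (stratum["label"] == "malignant").to_numpy()
        counts = (int((~y).sum()), int(y.sum()))
        if min(counts) < 2:
            raise ValueError(
                f"stratum {mass_type!r} needs >= 2 cases per class, got "
                f"benign={counts[0]}, malignant={counts[1]}"
            )
        panel = list(panels[mass_type])
        X = stratum[panel].to_numpy(dtype=float)

        # fold-wise CV with per-fold threshold selection
        n_splits = min(cfg.n_folds, min(counts))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=cfg.seed)
        cv_pred = np.zeros(len(y), dtype=bool)
        for train_idx, test_idx in skf.split(X, y):
            mean, scale, clf = _fit_one(X[train_idx], y[train_idx], cfg)
            s_train = _scores(clf, (X[train_idx] - mean) / scale, cfg)
            thr = choose_threshold(s_train, y[train_idx], cfg.specificity_floor)
            s_test = _scores(clf, (X[test_idx] - mean) / scale, cfg)
            cv_pred[test_idx] = s_test > thr
        sens = float(np.sum(cv_pred & y) / y.sum())
        spec = float(np.sum(~cv_pred & ~y) / (~y).sum())
        acc = float(np.mean(cv_pred == y))
        rows.append(
            {
                "mass_type": mass_type,
                "n": len(y),
                "n_malignant": counts[1],
                "cv_sensitivity": sens,
                "cv_specificity": spec,
                "cv_accuracy": acc,
            }
        )
        pooled_pred.append(cv_pred)
        pooled_true.append(y)

        # final refit on the whole stratum
        mean, scale, clf = _fit_one(X, y, cfg)
        s_all = _scores(clf, (X - mean) / scale, cfg)
        thr = choose_threshold(s_all, y, cfg.specificity_floor)
        if cfg.classifier == "random_forest":
            model = TypeModel(
                mass_type=mass_type, panel=panel, scaler_mean=mean,
                scaler_scale=scale, kind=cfg.classifier, threshold=thr,
                blob=pickle.dumps(clf),
            )
        else:
            model = TypeModel(
                mass_type=mass_type, panel=panel, scaler_mean=mean,
                scaler_scale=scale, kind=cfg.classifier, threshold=thr,
                coef=np.ravel(clf.coef_), intercept=float(clf.intercept_[0]),
            )
        models[mass_type] = model

    pred = np.concatenate(pooled_pred)
    true = np.concatenate(pooled_true)
    rows.append(
        {
            "mass_type": "pooled",
            "n": len(true),
            "n_malignant": int(true.sum()),
            "cv_sensitivity": float(np.sum(pred & true) / true.sum()),
            "cv_specificity": float(np.sum(~pred & ~true) / (~true).sum()),
            "cv_accuracy": float(np.mean(pred == true)),
        }
    )
    return TrainedEnsemble(models=models, config=cfg, cv_report=pd.DataFrame(rows))


def predict_radiomic(
    ensemble: TrainedEnsemble,
    features: FeatureVector | Mapping[str, float],
    mass_type: str,
) -> tuple[RiskClass, float]:
    """Ultrasound-only risk class + continuous score for one mass.

    The feature mapping must contain the full stable panel of the mass
    type; missing features raise (no imputation). Extra features and
    their ordering are irrelevant.
    """
    if mass_type not in ensemble.models:
        raise ValueError(f"no model for mass type {mass_type!r}")
    model = ensemble.models[mass_type]
    mapping = features.values if isinstance(features, FeatureVector) else features
    missing = [nm for nm in model.panel if nm not in mapping]
    if missing:
        raise ValueError(f"missing panel feature(s) for {mass_type}: {missing[:5]}")
    x = np.array([float(mapping[nm]) for nm in model.panel])
    score = model.score(x)
    risk = RiskClass.MEDIUM_HIGH if score > model.threshold else RiskClass.VERY_LOW
    return risk, score


def aggregate_variants(long_features: pd.DataFrame) -> pd.DataFrame:
    """Median-aggregate per-variant feature rows to one row per case.

    Expects columns ``case_id`` and ``variant`` plus feature columns; any
    other non-numeric columns (mass_type, label, ...) must be constant per
    case and are carried through.
    """
    meta_cols = [
        c
        for c in long_features.columns
        if c not in ("case_id", "variant")
        and not pd.api.types.is_numeric_dtype(long_features[c])
    ]
    feature_cols = [
        c
        for c in long_features.columns
        if c not in meta_cols and c not in ("case_id", "variant")
    ]
    grouped = long_features.groupby("case_id", sort=True)
    agg = grouped[feature_cols].median()
    out = grouped[meta_cols].first().join(agg) if meta_cols else agg
    return out.reset_index()
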