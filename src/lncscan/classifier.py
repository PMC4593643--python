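"""RBF-kernel SVM over the selected transcript features.

Training fits min/max scaling on the training matrix, then an RBF support
vector machine on the scaled features, optionally with a k-fold grid search
over (C, gamma) selecting the highest cross-validated accuracy.  The default
grid is the LIBSVM-community one for this problem class: C in 2^-1..2^7,
gamma in 2^-7..2^1.  The protein-coding class (PCT) is the positive class; a
transcript is labelled PCT iff its decision score is strictly positive.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from lncscan.features import ScalingParams, apply_scaler, fit_scaler

POSITIVE_LABEL = "PCT"
NEGATIVE_LABEL = "LNCT"
_LABEL_CODES = {NEGATIVE_LABEL: -1, POSITIVE_LABEL: 1}

_MODEL_FORMAT_VERSION = 1


class ModelIOError(ValueError):
    """Model file is corrupted, truncated, or of an unknown format version."""


@dataclass
class TrainConfig:
    """Grid-search and reproducibility settings for training."""

    c_grid: tuple[float, ...] = tuple(2.0**e for e in range(-1, 8))
    gamma_grid: tuple[float, ...] = tuple(2.0**e for e in range(-7, 2))
    cv_folds: int = 5
    grid_search: bool = True
    #: (C, gamma) used when grid_search is off.
    c: float = 1.0
    gamma: float = 0.5
    seed: int = 0


@dataclass
class TrainedModel:
    """A fitted SVM plus everything needed to apply it to new transcripts."""

    svm: SVC
    scaler: ScalingParams
    feature_names: tuple[str, ...]
    label_map: dict[int, str] = field(
        default_factory=lambda: {1: POSITIVE_LABEL, -1: NEGATIVE_LABEL}
    )
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.feature_names:
            raise ValueError("feature name list is empty")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")


def _validate_training_input(features: pd.DataFrame, labels: list[str]) -> None:
    if len(features) != len(labels):
        raise ValueError(
            f"{len(features)} feature rows but {len(labels)} labels"
        )
    unknown = set(labels) - set(_LABEL_CODES)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError(
            "training requires at least 2 samples in each of the PCT and "
            f"LNCT classes; got {counts.to_dict()}"
        )
    mask = features.isna()
    if mask.any().any():
        tid = mask.any(axis=1).idxmax()
        feat = mask.loc[tid].idxmax()
        raise ValueError(f"NaN feature {feat!r} for transcript {tid!r}")


def train(
    features: pd.DataFrame,
    labels: list[str],
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Fit scaling and the RBF-SVM; deterministic for a fixed seed."""
    config = config or TrainConfig()
    _validate_training_input(features, labels)
    y = np.array([_LABEL_CODES[lab] for lab in labels])
    scaler = fit_scaler(features)
    x = apply_scaler(scaler, features).to_numpy()

    if config.grid_search:
        cv = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed
        )
        search = GridSearchCV(
            SVC(kernel="rbf"),
            param_grid={"C": list(config.c_grid), "gamma": list(config.gamma_grid)},
            scoring="accuracy",
            cv=cv,
        )
        search.fit(x, y)
        svm = search.best_estimator_
        cv_accuracy = float(search.best_score_)
        c, gamma = svm.C, svm.gamma
    else:
        svm = SVC(kernel="rbf", C=config.c, gamma=config.gamma)
        svm.fit(x, y)
        cv_accuracy = float("nan")
        c, gamma = config.c, config.gamma

    n_pos = int((y == 1).sum())
    metadata = {
        "seed": config.seed,
        "date": datetime.date.today().isoformat(),
        "n_pos": n_pos,
        "n_neg": int(len(y) - n_pos),
        "C": float(c),
        "gamma": float(gamma),
        "cv_folds": config.cv_folds,
        "cv_accuracy": cv_accuracy,
    }
    return TrainedModel(
        svm=svm,
        scaler=scaler,
        feature_names=tuple(features.columns),
        metadata=metadata,
    )


def predict(
    model: TrainedModel, features: pd.DataFrame
) -> list[tuple[str, float]]:
    """Label and continuous decision score per row.

    The decision score is the signed distance from the SVM hyperplane in the
    scaled feature space; positive means PCT (a score of exactly 0 is
    labelled LNCT).  Scores are usable as a continuous ranking for ROC.
    """
    if tuple(features.columns) != model.feature_names:
        raise ValueError(
            f"feature mismatch: model expects {model.feature_names}, "
            f"got {tuple(features.columns)}"
        )
    if features.empty:
        return []
    x = apply_scaler(model.scaler, features).to_numpy()
    scores = model.svm.decision_function(x)
    return [
        (model.label_map[1] if s > 0 else model.label_map[-1], float(s))
        for s in scores
    ]


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model as a single self-describing archive."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "svm": model.svm,
        "scaler_limits": model.scaler.limits,
        "feature_names": model.feature_names,
        "label_map": model.label_map,
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    """Load a model archive; load(save(m)) predicts identically to m."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelIOError(f"{path} is not a model archive")
    if payload["format_version"] != _MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"unsupported model format version {payload['format_version']}"
        )
    return TrainedModel(
        svm=payload["svm"],
        scaler=ScalingParams(payload["scaler_limits"]),
        feature_names=tuple(payload["feature_names"]),
        label_map=dict(payload["label_map"]),
        metadata=dict(payload["metadata"]),
    )
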