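"""Hierarchical MET estimator: linear SVM intensity classifier followed by
one least-squares regression per intensity class.

The estimator mirrors a two-stage design for wrist-worn devices.  Minute
features (average of PA, variance of PA, step count — each log(1+x)
transformed — plus gender and BMI) first pass through a linear-kernel
support vector machine that assigns one of three intensity classes: SED,
LPA, or MVPA (moderate and vigorous collapsed).  The minute's METs are then
estimated by the ordinary-least-squares model trained for that class, and
the estimate is categorized against the standard MET cut-points:

    SED 0–1.49, LPA 1.50–2.99, MPA 3.00–5.99, VPA >= 6.00 METs.

The SVM regularization constant C is selected by grid search with
participant-grouped five-fold cross-validation (macro/balanced accuracy), so
no participant's minutes appear on both sides of a fold.  Per-class
regressions are fit on TRUE-class instances but applied by PREDICTED class
at inference, which keeps the regression stage free of classifier error
during fitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GroupKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .io import MinuteRecord
from .signal_features import MinuteFeatures
from .synthetic_trials import ParticipantProfile, TrialMinute

CATEGORIES = ("SED", "LPA", "MPA", "VPA")
CLASS3_ORDER = ("SED", "LPA", "MVPA")
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
MET_FLOOR = 0.5
N_FEATURES = 5
FEATURE_NAMES = ("log_pa_avg", "log_pa_var", "log_steps", "gender_code", "bmi")
#: gender is a 0/1 code and is not standardized
_CONTINUOUS = np.array([True, True, True, False, True])

MODEL_SCHEMA = "wristmet.hierarchical-met-model"
MODEL_SCHEMA_VERSION = 1


class TrainingError(ValueError):
    """The training set cannot support the model (e.g. a class is absent)."""


class SchemaError(ValueError):
    """A model file does not match the expected schema/version."""


@dataclass(frozen=True)
class IntensityThresholds:
    """Upper MET bounds of SED/LPA/MPA; VPA is everything above."""

    sed_max: float = 1.49
    lpa_max: float = 2.99
    mpa_max: float = 5.99

    def __post_init__(self) -> None:
        if not (0 < self.sed_max < self.lpa_max < self.mpa_max):
            raise ValueError("thresholds must be positive and strictly increasing")


DEFAULT_THRESHOLDS = IntensityThresholds()


def met_to_category(met: float, thresholds: IntensityThresholds = DEFAULT_THRESHOLDS) -> str:
    """Four-way intensity category of a MET value."""
    if not met > 0:
        raise ValueError("METs must be positive")
    if met <= thresholds.sed_max:
        return "SED"
    if met <= thresholds.lpa_max:
        return "LPA"
    if met <= thresholds.mpa_max:
        return "MPA"
    return "VPA"


def category_to_class3(category: str) -> str:
    """Collapse MPA and VPA into the MVPA classifier target."""
    if category in ("MPA", "VPA"):
        return "MVPA"
    if category in ("SED", "LPA"):
        return category
    raise ValueError(f"unknown category {category!r}")


@dataclass(frozen=True)
class FeatureVector:
    """Model input for one minute: log-scale watch features plus demographics."""

    log_pa_avg: float
    log_pa_var: float
    log_steps: float
    gender_code: int
    bmi: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.log_pa_avg, self.log_pa_var, self.log_steps, self.gender_code, self.bmi]
        )


def featurize(
    record: MinuteRecord | MinuteFeatures, participant: ParticipantProfile
) -> FeatureVector:
    """log(1+x) transform of the raw watch features, joined with gender/BMI.

    log(1+x) rather than log(x) because sedentary minutes legitimately have
    zero steps and near-zero PA features.
    """
    for name in ("pa_avg", "pa_var", "steps"):
        if getattr(record, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    return FeatureVector(
        log_pa_avg=float(np.log1p(record.pa_avg)),
        log_pa_var=float(np.log1p(record.pa_var)),
        log_steps=float(np.log1p(record.steps)),
        gender_code=participant.gender_code,
        bmi=participant.bmi,
    )


@dataclass(frozen=True)
class MetEstimate:
    predicted_class: str
    estimated_met: float
    category: str


@dataclass
class HierarchicalMetModel:
    """Fitted two-stage estimator, stored as plain arrays for exact
    serialization: one-vs-rest hyperplanes (3 x 5 weights + biases) and one
    6-coefficient OLS set (intercept first) per class, plus the feature
    standardization constants frozen from the training set."""

    group: str
    svm_weights: np.ndarray  # (3, 5), rows in CLASS3_ORDER
    svm_bias: np.ndarray  # (3,)
    regressors: dict[str, np.ndarray]  # class -> (6,) [intercept, 5 coefs]
    scaler_mean: np.ndarray  # (5,)
    scaler_scale: np.ndarray  # (5,)
    c: float
    cv_score: float
    seed: int | None
    train_participants: tuple[str, ...]
    thresholds: IntensityThresholds = field(default_factory=IntensityThresholds)

    def __post_init__(self) -> None:
        if set(self.regressors) != set(CLASS3_ORDER):
            raise ValueError(f"regressors must cover exactly {CLASS3_ORDER}")
        self.svm_weights = np.asarray(self.svm_weights, dtype=float)
        self.svm_bias = np.asarray(self.svm_bias, dtype=float)
        if self.svm_weights.shape != (len(CLASS3_ORDER), N_FEATURES):
            raise ValueError("svm_weights must be (3, 5)")

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """One-vs-rest margins, rows = minutes, columns in CLASS3_ORDER."""
        Xs = self._standardize(np.atleast_2d(X))
        return Xs @ self.svm_weights.T + self.svm_bias

    def predict_batch(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predicted class labels and estimated METs for raw feature rows.

        Ties in the one-vs-rest margins break toward the earlier class in
        SED < LPA < MVPA order.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        margins = self.decision_function(X)
        idx = np.argmax(margins, axis=1)
        Xs = self._standardize(X)
        design = np.hstack([np.ones((Xs.shape[0], 1)), Xs])
        mets = np.empty(X.shape[0])
        for k, cls in enumerate(CLASS3_ORDER):
            mask = idx == k
            if mask.any():
                mets[mask] = design[mask] @ self.regressors[cls]
        mets = np.maximum(mets, MET_FLOOR)
        classes = np.array([CLASS3_ORDER[k] for k in idx])
        return classes, mets


def estimate(model: HierarchicalMetModel, features: FeatureVector) -> MetEstimate:
    """Classify one minute, regress METs with the predicted class's model,
    clamp to the physiological floor, and categorize the estimate."""
    classes, mets = model.predict_batch(features.as_array()[None, :])
    met = float(mets[0])
    return MetEstimate(
        predicted_class=str(classes[0]),
        estimated_met=met,
        category=met_to_category(met, model.thresholds),
    )


def build_design(
    minutes: Sequence[TrialMinute], participants: Sequence[ParticipantProfile]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw feature matrix, true METs, and participant ids for model fitting."""
    by_id = {p.id: p for p in participants}
    X = np.empty((len(minutes), N_FEATURES))
    y = np.empty(len(minutes))
    groups = np.empty(len(minutes), dtype=object)
    for i, m in enumerate(minutes):
        if m.record is None:
            raise TrainingError(f"minute {i} has no watch record")
        fv = featurize(m.record, by_id[m.participant_id])
        X[i] = fv.as_array()
        y[i] = m.true_met
        groups[i] = m.participant_id
    return X, y, groups


def _ols(design: np.ndarray, target: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    return coef


def train(
    minutes: Sequence[TrialMinute],
    participants: Sequence[ParticipantProfile],
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    n_folds: int = 5,
    thresholds: IntensityThresholds = DEFAULT_THRESHOLDS,
) -> HierarchicalMetModel:
    """Fit the full hierarchical model on labeled training minutes.

    Class labels derive from the criterion METs via the cut-points (with MPA
    and VPA collapsed).  C is chosen from ``c_grid`` by participant-grouped
    cross-validation maximizing macro (balanced) accuracy, ties toward the
    smaller C; per-class OLS solves use the minutes whose TRUE class matches.
    The fit is deterministic given data and seed.
    """
    if len({m.participant_id for m in minutes}) < 2:
        raise TrainingError("training requires minutes from at least 2 participants")
    X, y_met, groups = build_design(minutes, participants)
    y3 = np.array([category_to_class3(met_to_category(m, thresholds)) for m in y_met])
    missing = [c for c in CLASS3_ORDER if c not in set(y3)]
    if missing:
        raise TrainingError(
            f"training set has no instances of class(es): {', '.join(missing)}"
        )

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    scaler_mean = np.where(_CONTINUOUS, mean, 0.0)
    scaler_scale = np.where(_CONTINUOUS & (sd > 0), sd, 1.0)
    Xs = (X - scaler_mean) / scaler_scale
    y_codes = np.array([CLASS3_ORDER.index(c) for c in y3])

    n_groups = len(np.unique(groups))
    splitter = GroupKFold(n_splits=min(n_folds, n_groups))
    best_c, best_score = None, -np.inf
    for c in c_grid:
        scores = []
        for tr, va in splitter.split(Xs, y_codes, groups):
            if len(np.unique(y_codes[tr])) < len(CLASS3_ORDER):
                continue  # degenerate fold: a class entirely in validation
            clf = OneVsRestClassifier(SVC(kernel="linear", C=c))
            clf.fit(Xs[tr], y_codes[tr])
            with warnings.catch_warnings():
                # a small validation fold may miss a class; macro accuracy
                # over the present classes is the intended behavior
                warnings.simplefilter("ignore", UserWarning)
                scores.append(
                    balanced_accuracy_score(y_codes[va], clf.predict(Xs[va]))
                )
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score + 1e-12:
            best_c, best_score = c, score
    if best_c is None:
        raise TrainingError("cross-validation produced no usable folds")

    final = OneVsRestClassifier(SVC(kernel="linear", C=best_c))
    final.fit(Xs, y_codes)
    weights = np.vstack([est.coef_ for est in final.estimators_])
    bias = np.concatenate([est.intercept_ for est in final.estimators_])

    design = np.hstack([np.ones((Xs.shape[0], 1)), Xs])
    regressors = {
        cls: _ols(design[y3 == cls], y_met[y3 == cls]) for cls in CLASS3_ORDER
    }

    return HierarchicalMetModel(
        group=participants[0].group if participants else "unknown",
        svm_weights=weights,
        svm_bias=bias,
        regressors=regressors,
        scaler_mean=scaler_mean,
        scaler_scale=scaler_scale,
        c=float(best_c),
        cv_score=best_score,
        seed=seed,
        train_participants=tuple(sorted({m.participant_id for m in minutes})),
        thresholds=thresholds,
    )


def save_model(model: HierarchicalMetModel, path: str | Path) -> None:
    """Versioned JSON serialization; float lists preserve full precision."""
    payload = {
        "schema": MODEL_SCHEMA,
        "schema_version": MODEL_SCHEMA_VERSION,
        "group": model.group,
        "svm_weights": model.svm_weights.tolist(),
        "svm_bias": model.svm_bias.tolist(),
        "regressors": {k: v.tolist() for k, v in model.regressors.items()},
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "c": model.c,
        "cv_score": model.cv_score,
        "seed": model.seed,
        "train_participants": list(model.train_participants),
        "thresholds": {
            "sed_max": model.thresholds.sed_max,
            "lpa_max": model.thresholds.lpa_max,
            "mpa_max": model.thresholds.mpa_max,
        },
        "feature_names": list(FEATURE_NAMES),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_model(path: str | Path) -> HierarchicalMetModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid model JSON: {exc}") from exc
    if not isinstance(payload, Mapping) or "schema_version" not in payload:
        raise SchemaError(f"{path}: missing schema version field")
    if (
        payload.get("schema") != MODEL_SCHEMA
        or payload["schema_version"] != MODEL_SCHEMA_VERSION
    ):
        raise SchemaError(
            f"{path}: expected {MODEL_SCHEMA} v{MODEL_SCHEMA_VERSION}, got "
            f"{payload.get('schema')!r} v{payload.get('schema_version')!r}"
        )
    return HierarchicalMetModel(
        group=payload["group"],
        svm_weights=np.array(payload["svm_weights"]),
        svm_bias=np.array(payload["svm_bias"]),
        regressors={k: np.array(v) for k, v in payload["regressors"].items()},
        scaler_mean=np.array(payload["scaler_mean"]),
        scaler_scale=np.array(payload["scaler_scale"]),
        c=float(payload["c"]),
        cv_score=float(payload["cv_score"]),
        seed=payload["seed"],
        train_participants=tuple(payload["train_participants"]),
        thresholds=IntensityThresholds(**payload["thresholds"]),
    )
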