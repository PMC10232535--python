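"""Source-domain selectivity regression: algorithm zoo, k-fold CV, model fit.

The base model learns the structure–performance relationship (SPR) of the
already-optimised source reaction from its accumulated screening records:
features are the 108-dimensional physical-organic encoding, the target is
ΔΔG in kcal/mol.  Candidate algorithms are compared by shuffled k-fold
cross-validation on pooled out-of-fold predictions, ranked by Pearson R
(ties broken by MAE); linear support vector regression is the default
winner for near-linear SPRs.

Features are standardised inside each training fold only — scaler statistics
never see held-out rows — and the final model refits scaler and regressor on
the full training set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .reaction_data import EncodedDataset, EncodedReaction

__all__ = [
    "RegressorSpec",
    "DEFAULT_ZOO",
    "ConstantInputError",
    "pearson_r",
    "mae",
    "CVReport",
    "kfold_cv",
    "rank_algorithms",
    "BaseModel",
    "fit_base",
    "predict_base",
    "save_model",
    "load_model",
]


class ConstantInputError(ValueError):
    """Pearson correlation is undefined when either vector is constant."""


def pearson_r(a, b) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raises :class:`ConstantInputError` on a constant input rather than
    returning NaN, so degeneracy surfaces explicitly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("pearson_r needs two 1-D vectors of equal length")
    if a.size < 2:
        raise ValueError("pearson_r needs at least 2 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    return float(stats.pearsonr(a, b).statistic)


def mae(a, b) -> float:
    """Mean absolute error, in the units of the inputs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mae needs equal-length vectors")
    return float(np.mean(np.abs(a - b)))


# ---------------------------------------------------------------------------
# Regressor specifications

_ALGORITHM_DEFAULTS: dict[str, dict] = {
    "linear_svr": {"C": 1.0, "epsilon": 0.1},
    "ridge": {"alpha": 1.0},
    "lasso": {"alpha": 0.01, "max_iter": 100_000},
    "kernel_svr": {"C": 1.0, "epsilon": 0.1, "gamma": "scale"},
    "random_forest": {"n_estimators": 200},
    "gradient_boosting": {"n_estimators": 200, "learning_rate": 0.05},
    "k_neighbors": {"n_neighbors": 5},
}


@dataclass(frozen=True)
class RegressorSpec:
    """Named algorithm + hyperparameters + scaling choice.

    Hyperparameters are validated against the algorithm's known keys; unknown
    algorithms or parameters raise immediately, before any data is touched.
    """

    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    scaling: str = "standardize"

    def __post_init__(self):
        if self.algorithm not in _ALGORITHM_DEFAULTS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; "
                f"choose from {sorted(_ALGORITHM_DEFAULTS)}"
            )
        unknown = set(self.hyperparameters) - set(_ALGORITHM_DEFAULTS[self.algorithm])
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for {self.algorithm}: {sorted(unknown)}"
            )
        if self.scaling not in ("standardize", "none"):
            raise ValueError("scaling must be 'standardize' or 'none'")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))

    def resolved_hyperparameters(self) -> dict:
        params = dict(_ALGORITHM_DEFAULTS[self.algorithm])
        params.update(self.hyperparameters)
        return params

    def make_estimator(self, seed: int = 0):
        """Instantiate the scikit-learn estimator (seeded where stochastic)."""
        p = self.resolved_hyperparameters()
        if self.algorithm == "linear_svr":
            return SVR(kernel="linear", C=p["C"], epsilon=p["epsilon"])
        if self.algorithm == "ridge":
            return Ridge(alpha=p["alpha"])
        if self.algorithm == "lasso":
            return Lasso(alpha=p["alpha"], max_iter=p["max_iter"])
        if self.algorithm == "kernel_svr":
            return SVR(kernel="rbf", C=p["C"], epsilon=p["epsilon"], gamma=p["gamma"])
        if self.algorithm == "random_forest":
            return RandomForestRegressor(
                n_estimators=p["n_estimators"], random_state=seed
            )
        if self.algorithm == "gradient_boosting":
            return GradientBoostingRegressor(
                n_estimators=p["n_estimators"],
                learning_rate=p["learning_rate"],
                random_state=seed,
            )
        if self.algorithm == "k_neighbors":
            return KNeighborsRegressor(n_neighbors=p["n_neighbors"])
        raise AssertionError(self.algorithm)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "hyperparameters": dict(self.hyperparameters),
            "scaling": self.scaling,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegressorSpec":
        return cls(
            algorithm=d["algorithm"],
            hyperparameters=d.get("hyperparameters", {}),
            scaling=d.get("scaling", "standardize"),
        )


def default_zoo() -> list[RegressorSpec]:
    """The seven conventional candidate algorithms with default settings."""
    return [RegressorSpec(name) for name in _ALGORITHM_DEFAULTS]


DEFAULT_ZOO = tuple(_ALGORITHM_DEFAULTS)


# ---------------------------------------------------------------------------
# Scaling helper (kept explicit so fitted statistics serialise to JSON)


class _IdentityScaler:
    """No-op stand-in so every fitted model carries scaler parameters."""

    def fit(self, X):
        self.mean_ = np.zeros(X.shape[1])
        self.scale_ = np.ones(X.shape[1])
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)


def _make_scaler(spec: RegressorSpec):
    # StandardScaler maps zero-variance columns to zero (scale_ forced to 1),
    # so constant descriptor columns never divide by zero.
    return StandardScaler() if spec.scaling == "standardize" else _IdentityScaler()


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class CVReport:
    """Out-of-fold predictions and pooled metrics for one spec.

    ``pearson_r`` is None (with ``pearson_defined`` False) when the pooled
    predictions or targets are constant.
    """

    spec: RegressorSpec
    k: int
    seed: int
    per_sample_prediction: Mapping[str, float]
    fold_assignment: Mapping[str, int]
    pearson_r: float | None
    mae: float

    @property
    def pearson_defined(self) -> bool:
        return self.pearson_r is not None


def kfold_cv(
    dataset: EncodedDataset, spec: RegressorSpec, k: int = 10, seed: int = 0
) -> CVReport:
    """Shuffled k-fold cross-validation with per-fold scaling.

    Every record lands in exactly one test fold (fold sizes differ by at most
    one); the scaler and regressor are fit on the training folds only and
    metrics are computed on the pooled out-of-fold predictions.  ``k = n``
    reduces to leave-one-out.
    """
    n = dataset.n
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds dataset size n = {n}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.empty(n)
    folds = np.empty(n, dtype=int)
    for fold_idx, (train, test) in enumerate(splitter.split(dataset.X)):
        scaler = _make_scaler(spec).fit(dataset.X[train])
        est = spec.make_estimator(seed=seed)
        est.fit(scaler.transform(dataset.X[train]), dataset.y[train])
        preds[test] = est.predict(scaler.transform(dataset.X[test]))
        folds[test] = fold_idx
    try:
        r = pearson_r(dataset.y, preds)
    except ConstantInputError:
        r = None
    return CVReport(
        spec=spec,
        k=k,
        seed=seed,
        per_sample_prediction=dict(zip(dataset.reaction_ids, preds.tolist())),
        fold_assignment=dict(zip(dataset.reaction_ids, folds.tolist())),
        pearson_r=r,
        mae=mae(dataset.y, preds),
    )


def rank_algorithms(
    dataset: EncodedDataset,
    specs: Sequence[RegressorSpec],
    k: int = 10,
    seed: int = 0,
) -> list[CVReport]:
    """CV every spec and sort by descending Pearson R, then ascending MAE.

    Undefined correlations sort last; remaining ties keep input order
    (stable sort), so duplicate specs preserve their relative position.
    """
    if not specs:
        raise ValueError("need at least one RegressorSpec")
    reports = [kfold_cv(dataset, spec, k=k, seed=seed) for spec in specs]
    return sorted(
        reports,
        key=lambda rep: (
            -(rep.pearson_r if rep.pearson_r is not None else -np.inf),
            rep.mae,
        ),
    )


# ---------------------------------------------------------------------------
# Final fit and persistence


@dataclass
class BaseModel:
    """Fitted scaler + regressor over a fixed encoding schema."""

    spec: RegressorSpec
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    estimator: object
    column_names: tuple[str, ...]
    training_fingerprint: str

    @property
    def n_features(self) -> int:
        return int(self.scaler_mean.shape[0])

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"encoding width {X.shape[-1]} does not match the model's "
                f"training schema ({self.n_features} features)"
            )
        return np.asarray(
            self.estimator.predict((X - self.scaler_mean) / self.scaler_scale)
        )


def _fingerprint(dataset: EncodedDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.X).tobytes())
    h.update(np.ascontiguousarray(dataset.y).tobytes())
    return h.hexdigest()[:16]


def fit_base(dataset: EncodedDataset, spec: RegressorSpec, seed: int = 0) -> BaseModel:
    """Fit scaler on the full dataset, then the regressor on scaled features."""
    if dataset.n == 0:
        raise ValueError("cannot fit on an empty dataset")
    scaler = _make_scaler(spec).fit(dataset.X)
    est = spec.make_estimator(seed=seed)
    est.fit(scaler.transform(dataset.X), dataset.y)
    return BaseModel(
        spec=spec,
        scaler_mean=np.asarray(scaler.mean_, dtype=float),
        scaler_scale=np.asarray(scaler.scale_, dtype=float),
        estimator=est,
        column_names=dataset.column_names,
        training_fingerprint=_fingerprint(dataset),
    )


def predict_base(model: BaseModel, encoded: EncodedReaction | np.ndarray) -> float:
    """Predict ΔΔG (kcal/mol) for one encoded reaction."""
    vec = encoded.vector if isinstance(encoded, EncodedReaction) else np.asarray(encoded)
    return float(model.predict_matrix(vec.reshape(1, -1))[0])


_LINEAR_ALGOS = ("linear_svr", "ridge", "lasso")

_MODEL_FORMAT = "chirtransfer-model"
_MODEL_VERSION = 1


def save_model(model: BaseModel, path) -> None:
    """Serialise a linear model to versioned JSON (scaler stats + weights).

    Only linear algorithms (linear_svr, ridge, lasso) have a stable flat
    weight representation; tree and kernel models are not JSON-persistable.
    """
    if model.spec.algorithm not in _LINEAR_ALGOS:
        raise ValueError(
            f"JSON persistence supports linear models {_LINEAR_ALGOS}; "
            f"got {model.spec.algorithm!r}"
        )
    coef = np.ravel(model.estimator.coef_)
    intercept = float(np.ravel(model.estimator.intercept_)[0])
    payload = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "spec": model.spec.to_dict(),
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "coef": coef.tolist(),
        "intercept": intercept,
        "column_names": list(model.column_names),
        "training_fingerprint": model.training_fingerprint,
    }
    Path(path).write_text(json.dumps(payload))


class _LinearPredictor:
    """Minimal linear predictor reconstructed from serialised weights."""

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef_ = np.asarray(coef, dtype=float)
        self.intercept_ = np.array([intercept])

    def predict(self, X):
        return X @ self.coef_ + self.intercept_[0]


def load_model(path) -> BaseModel:
    """Reload a JSON-serialised model with bit-identical predictions."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not a {_MODEL_FORMAT} file")
    return BaseModel(
        spec=RegressorSpec.from_dict(payload["spec"]),
        scaler_mean=np.array(payload["scaler_mean"], dtype=float),
        scaler_scale=np.array(payload["scaler_scale"], dtype=float),
        estimator=_LinearPredictor(payload["coef"], payload["intercept"]),
        column_names=tuple(payload["column_names"]),
        training_fingerprint=payload["training_fingerprint"],
    )
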