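"""Downstream regressors mapping feature matrices to knee angles in degrees.

The network's fusion output is only a training signal for feature learning;
the angle estimate reported everywhere comes from one of five regressors
(RF, LightGBM, MLP, SVR, KNN) fitted on the feature matrix.  Features are
z-scored by training statistics inside the wrapper; targets stay in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .exceptions import DimensionError, NumericError, ParameterError

REGRESSOR_KINDS = ("RF", "LGBM", "MLP", "SVR", "KNN")

# Hyperparameter defaults.  The regression-forest settings follow the classic
# Breiman recommendation (max_features = d/3) with a moderate ensemble size
# sized for a single core; everything is overridable through RegressorSpec.
_DEFAULTS = {
    "RF": dict(n_estimators=200, max_features=1 / 3, min_samples_leaf=2),
    "LGBM": dict(n_estimators=500, learning_rate=0.05),
    "MLP": dict(hidden_layer_sizes=(64,), learning_rate_init=1e-3, max_iter=500),
    "SVR": dict(kernel="rbf", C=10.0, gamma="scale"),
    "KNN": dict(n_neighbors=5),
}


@dataclass
class RegressorSpec:
    """Which regressor to fit and with which hyperparameters."""

    kind: str = "RF"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in REGRESSOR_KINDS:
            raise ParameterError(f"kind must be one of {REGRESSOR_KINDS}")

    def resolved(self) -> dict:
        hp = dict(_DEFAULTS[self.kind])
        hp.update(self.hyperparameters)
        return hp


def _build_estimator(spec: RegressorSpec):
    hp = spec.resolved()
    if spec.kind == "RF":
        return RandomForestRegressor(random_state=spec.seed, n_jobs=1, **hp)
    if spec.kind == "LGBM":
        import lightgbm as lgb

        return lgb.LGBMRegressor(random_state=spec.seed, n_jobs=1, verbose=-1, **hp)
    if spec.kind == "MLP":
        return MLPRegressor(random_state=spec.seed, **hp)
    if spec.kind == "SVR":
        return SVR(**hp)
    return KNeighborsRegressor(**hp)


class AngleRegressor:
    """A fitted regressor plus the training-set feature standardization."""

    def __init__(self, spec: RegressorSpec):
        self.spec = spec
        self.n_features_: int | None = None

    def fit(self, features, targets_deg) -> "AngleRegressor":
        X = np.asarray(features, dtype=float)
        y = np.asarray(targets_deg, dtype=float).ravel()
        if X.ndim != 2:
            raise DimensionError("features must be a 2-D matrix")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise NumericError("non-finite features or targets")
        if X.shape[0] < 10:
            raise ParameterError("need at least 10 training rows")
        if X.shape[0] != y.size:
            raise DimensionError("feature rows and target length differ")
        self.n_features_ = X.shape[1]
        self._mean = X.mean(axis=0)
        self._std = X.std(axis=0)
        self._std[self._std == 0] = 1.0
        self._est = _build_estimator(self.spec)
        self._est.fit((X - self._mean) / self._std, y)
        return self

    def predict(self, features) -> np.ndarray:
        if self.n_features_ is None:
            raise DimensionError("regressor not fitted")
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise DimensionError(
                f"expected {self.n_features_} feature columns, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-matrix'}"
            )
        if not np.all(np.isfinite(X)):
            raise NumericError("non-finite features")
        return np.asarray(self._est.predict((X - self._mean) / self._std), dtype=float)


def fit_regressor(features, targets_deg, spec: RegressorSpec | None = None) -> AngleRegressor:
    """Fit one regressor on (N, d) features and degree targets."""
    return AngleRegressor(spec or RegressorSpec()).fit(features, targets_deg)


def predict_angles(model: AngleRegressor, features) -> np.ndarray:
    """Predict knee angles in degrees for a feature matrix."""
    return model.predict(features)
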