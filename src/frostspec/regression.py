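"""Uniform fit/predict surface over the six regression families.

PLS is native (NIPALS, :mod:`frostspec.pls`); SVM, RF and BP are backed by
scikit-learn; the CNN and LSTM are the numpy implementations in
:mod:`frostspec.nets`. Family defaults ship in ``data/model_defaults.yaml``.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from . import pls as _pls
from .nets import CNNRegressor, LSTMRegressor

FAMILIES = ("PLS", "SVM", "RF", "BP", "CNN", "LSTM")


class RegressionError(RuntimeError):
    pass


def load_default_params() -> dict:
    """Shipped per-family default parameter maps."""
    path = importlib.resources.files("frostspec") / "data" / "model_defaults.yaml"
    with open(str(path)) as fh:
        return yaml.safe_load(fh)


@dataclass
class RegressorSpec:
    """One grid model: family name, parameter overrides, seed."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.family = self.family.upper()
        if self.family not in FAMILIES:
            raise RegressionError(f"unknown model family {self.family!r}")
        defaults = load_default_params()[self.family]
        unknown = set(self.params) - set(defaults)
        if unknown:
            raise RegressionError(
                f"unknown parameter(s) {sorted(unknown)} for family {self.family}"
            )
        self.resolved = {**defaults, **self.params}


@dataclass
class FittedModel:
    """Fitted state plus the metadata predict() validates against."""

    spec: RegressorSpec
    estimator: object
    n_bands: int
    n_train: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_bands:
            got = X.shape[1] if X.ndim == 2 else None
            raise RegressionError(
                f"band-axis mismatch: model was trained on {self.n_bands} bands, got {got}"
            )
        return np.asarray(self.estimator.predict(X), dtype=float).ravel()


def _fit_pls(X, y, p, seed):
    a = _pls.max_components(X.shape[0], X.shape[1], int(p["n_components"]))
    return _pls.pls_fit(X, y, a, scale=bool(p["scale"]),
                        max_iter=int(p["max_iter"]), tol=float(p["tol"]))


def _fit_svm(X, y, p, seed):
    model = SVR(kernel=p["kernel"], degree=int(p["degree"]), C=float(p["C"]),
                tol=float(p["tol"]), cache_size=float(p["cache_size"]),
                max_iter=int(p["max_iter"]))
    return model.fit(X, y)


def _fit_rf(X, y, p, seed):
    model = RandomForestRegressor(
        n_estimators=int(p["n_estimators"]),
        min_samples_leaf=int(p["min_samples_leaf"]),
        n_jobs=int(p["n_jobs"]),
        max_samples=p["max_samples"],
        random_state=seed,
    )
    return model.fit(X, y)


def _fit_bp(X, y, p, seed):
    model = MLPRegressor(
        hidden_layer_sizes=(int(p["hidden_units"]),),
        solver=p["solver"],
        learning_rate_init=float(p["learning_rate"]),
        batch_size=min(int(p["batch_size"]), X.shape[0]),
        max_iter=int(p["epochs"]),
        tol=float(p["goal"]),
        random_state=seed,
        momentum=0.0,
    )
    with warnings.catch_warnings():
        # epoch count is fixed by design (no early stopping)
        warnings.simplefilter("ignore", ConvergenceWarning)
        return model.fit(X, y)


def _fit_cnn(X, y, p, seed):
    model = CNNRegressor(
        channels=tuple(p["channels"]), kernel_size=int(p["kernel_size"]),
        pool_size=int(p["pool_size"]), learning_rate=float(p["learning_rate"]),
        batch_size=int(p["batch_size"]), epochs=int(p["epochs"]),
        dropout=float(p["dropout"]), seed=seed,
    )
    return model.fit(X, y)


def _fit_lstm(X, y, p, seed):
    model = LSTMRegressor(
        hidden_units=int(p["hidden_units"]), learning_rate=float(p["learning_rate"]),
        batch_size=int(p["batch_size"]), epochs=int(p["epochs"]),
        dropout=float(p["dropout"]), seed=seed,
    )
    return model.fit(X, y)


_FITTERS = {"PLS": _fit_pls, "SVM": _fit_svm, "RF": _fit_rf, "BP": _fit_bp,
            "CNN": _fit_cnn, "LSTM": _fit_lstm}


def fit(spec: RegressorSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    """Fit one regression family; raises with family context on failure."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise RegressionError(f"{spec.family}: non-finite values in X or y")
    try:
        estimator = _FITTERS[spec.family](X, y, spec.resolved, spec.seed)
    except Exception as exc:  # surface family context
        raise RegressionError(f"{spec.family} fit failed: {exc}") from exc
    return FittedModel(spec=spec, estimator=estimator, n_bands=X.shape[1],
                       n_train=X.shape[0])


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)
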