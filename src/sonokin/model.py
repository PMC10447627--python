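"""Per-joint-variable regression network: 192 features -> one kinematic value.

The network is deliberately small — three fully connected 10-node layers
with ReLU activations and a single linear output (2161 trainable
parameters) — trained by minimizing mean squared error on per-feature
standardized inputs.  One independent model is trained per joint
variable (knee/ankle position and velocity); velocity models are not
derivatives of position models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .errors import InsufficientDataError, NonFiniteError, ParseError, ShapeError
from .stream import SupervisedDataset


@dataclass
class RegressorConfig:
    """Training configuration for one regression network."""

    hidden_widths: tuple[int, ...] = (10, 10, 10)
    activation: str = "relu"
    solver: str = "lbfgs"
    max_iter: int = 1000
    tol: float = 1e-6
    alpha: float = 0.0
    standardize: bool = True
    min_rows: int = 100
    seed: int | None = None


class KinematicsRegressor(RegressorMixin, BaseEstimator):
    """Small MLP regressor with per-feature input standardization.

    Parameters mirror :class:`RegressorConfig`; defaults give the
    192->10->10->10->1 ReLU architecture trained full-batch by L-BFGS on
    MSE with no explicit regularization, deterministic for a fixed
    random_state.

    Fitted attributes: ``scaler_`` (or None), ``net_`` (the underlying
    MLP), ``n_parameters_`` (2161 for the default widths at 192 inputs),
    ``loss_trace_`` (final training loss; L-BFGS exposes no per-iteration
    curve), ``converged_``.
    """

    def __init__(self, hidden_widths=(10, 10, 10), activation="relu", solver="lbfgs",
                 max_iter=1000, tol=1e-6, alpha=0.0, standardize=True,
                 min_rows=100, random_state=None, variable_name=None):
        self.hidden_widths = hidden_widths
        self.activation = activation
        self.solver = solver
        self.max_iter = max_iter
        self.tol = tol
        self.alpha = alpha
        self.standardize = standardize
        self.min_rows = min_rows
        self.random_state = random_state
        self.variable_name = variable_name

    def _check_X(self, X, n_features: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ShapeError(f"expected 2-D feature rows, got shape {X.shape}")
        if n_features is not None and X.shape[1] != n_features:
            raise ShapeError(
                f"expected rows of width {n_features}, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise NonFiniteError("feature rows contain non-finite values")
        return X

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ShapeError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
        if not np.all(np.isfinite(y)):
            raise NonFiniteError("labels contain non-finite values")
        if X.shape[0] < self.min_rows:
            raise InsufficientDataError(
                f"need at least {self.min_rows} rows to fit, got {X.shape[0]}")
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        self.net_ = MLPRegressor(hidden_layer_sizes=tuple(self.hidden_widths),
                                 activation=self.activation, solver=self.solver,
                                 alpha=self.alpha, max_iter=self.max_iter,
                                 tol=self.tol, random_state=self.random_state)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            self.net_.fit(Xs, y)
        self.converged_ = not any(issubclass(w.category, ConvergenceWarning)
                                  for w in caught)
        self.loss_trace_ = list(getattr(self.net_, "loss_curve_", [self.net_.loss_]))
        if not self.converged_:
            self.loss_trace_.append(float("nan"))  # sentinel: max_iter hit
        self.n_parameters_ = int(sum(c.size for c in self.net_.coefs_)
                                 + sum(b.size for b in self.net_.intercepts_))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = self._check_X(X, self.n_features_in_)
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        return self.net_.predict(Xs)


def train_regressor(dataset: SupervisedDataset, config: RegressorConfig | None = None
                    ) -> KinematicsRegressor:
    """Fit one network on a supervised dataset (thin wrapper)."""
    cfg = config or RegressorConfig()
    reg = KinematicsRegressor(hidden_widths=cfg.hidden_widths, activation=cfg.activation,
                              solver=cfg.solver, max_iter=cfg.max_iter, tol=cfg.tol,
                              alpha=cfg.alpha, standardize=cfg.standardize,
                              min_rows=cfg.min_rows, random_state=cfg.seed,
                              variable_name=dataset.variable_name)
    return reg.fit(dataset.X, dataset.y)


def predict(model: KinematicsRegressor, X) -> np.ndarray:
    """Apply a fitted network to feature rows (thin wrapper)."""
    return model.predict(X)


def save_regressor(model: KinematicsRegressor, path) -> None:
    """Serialize architecture, standardization and weights to JSON."""
    check_is_fitted(model, "net_")
    payload = {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()},
        "n_features_in": int(model.n_features_in_),
        "scaler": None if model.scaler_ is None else {
            "mean": model.scaler_.mean_.tolist(),
            "scale": model.scaler_.scale_.tolist()},
        "coefs": [c.tolist() for c in model.net_.coefs_],
        "intercepts": [b.tolist() for b in model.net_.intercepts_],
        "converged": bool(model.converged_),
    }
    Path(path).write_text(json.dumps(payload))


def load_regressor(path) -> KinematicsRegressor:
    """Rebuild a serialized regressor; predictions match the saved model."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"model file {path} does not exist")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed model file {path}: {exc}") from exc
    params = dict(payload["params"])
    params["hidden_widths"] = tuple(params["hidden_widths"])
    model = KinematicsRegressor(**params)
    n_in = payload["n_features_in"]
    coefs = [np.asarray(c) for c in payload["coefs"]]
    intercepts = [np.asarray(b) for b in payload["intercepts"]]
    net = MLPRegressor(hidden_layer_sizes=tuple(model.hidden_widths),
                       activation=model.activation, solver=model.solver,
                       alpha=model.alpha, max_iter=1, tol=model.tol)
    # fit on a dummy batch to build internals, then overwrite the weights
    rng = np.random.default_rng(0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net.fit(rng.normal(size=(8, n_in)), rng.normal(size=8))
    net.coefs_ = coefs
    net.intercepts_ = intercepts
    model.net_ = net
    model.n_features_in_ = n_in
    if payload["scaler"] is None:
        model.scaler_ = None
    else:
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(payload["scaler"]["mean"])
        scaler.scale_ = np.asarray(payload["scaler"]["scale"])
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = n_in
        model.scaler_ = scaler
    model.converged_ = payload["converged"]
    model.loss_trace_ = []
    model.n_parameters_ = int(sum(c.size for c in coefs)
                              + sum(b.size for b in intercepts))
    return model
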