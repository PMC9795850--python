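"""Yield-parameter regression: five model families and their metrics.

Each method is wrapped in :class:`YieldRegressor`, a sklearn-style estimator
that standardizes features on the training set and fits one of:

* ``plsr`` — partial least squares with up to 5 components, the count chosen
  by leave-one-out cross-validation on the training set;
* ``lasso`` — L1-penalized linear regression over a 10-fold cross-validated
  regularization path (the continuous-target analogue of a lambda-path
  penalized GLM);
* ``rf`` — random forest, 500 trees, one-third of the features tried per
  split;
* ``svr`` — radial-basis support-vector regression, gamma = 1/p,
  epsilon-insensitive loss with epsilon 0.01, tolerance 1e-3;
* ``mlp`` — feed-forward network with two 200-neuron hidden layers trained
  for 10 epochs of stochastic gradient descent at learning rate 0.005.

Evaluation reports R^2 = 1 - SSres/SStot, RMSE, and the relative RMSE
rRMSE = 100 * RMSE / mean(observed) (percent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV
from sklearn.model_selection import LeaveOneOut, train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, ModelError

#: canonical method keys, in reporting order
METHODS = ("plsr", "lasso", "rf", "svr", "mlp")

METHOD_LABELS = {
    "plsr": "partial least squares",
    "lasso": "penalized linear (CV lasso)",
    "rf": "random forest",
    "svr": "support vector regression",
    "mlp": "neural network",
}


@dataclass(frozen=True)
class ModelSpec:
    """A method choice plus seed and optional parameter overrides."""

    method: str = "rf"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}; valid: {METHODS}")


@dataclass
class ModelResult:
    """Metrics and predictions of one method on one feature set and target."""

    method: str
    feature_set: str
    target: str
    n_features: int
    train_metrics: dict[str, float]
    validation_metrics: dict[str, float]
    predictions: pd.DataFrame  # plot_id, split, observed, predicted


def split_data(
    table: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, by-plot train/validation split (floor on train)."""
    if not (0 < train_fraction < 1):
        raise ConfigurationError("train_fraction must lie strictly between 0 and 1")
    if len(table) < 10:
        raise ModelError("need at least 10 rows to split")
    train, val = train_test_split(table, train_size=train_fraction, random_state=seed)
    return train, val


def regression_metrics(observed, predicted) -> dict[str, float]:
    """R^2, RMSE and rRMSE (%) between paired observed/predicted values.

    rRMSE is NaN-flagged when the observed mean is zero (undefined scale).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ModelError("observed and predicted lengths differ")
    if obs.size < 2:
        raise ModelError("need at least 2 pairs")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    mean_obs = float(obs.mean())
    rrmse = 100.0 * rmse / mean_obs if mean_obs != 0 else float("nan")
    return {"r2": r2, "rmse": rmse, "rrmse": rrmse}


class YieldRegressor(BaseEstimator, RegressorMixin):
    """One of the five regression families behind a common fit/predict surface.

    Features are standardized with statistics fitted on the training data
    only; targets are left untransformed.  All stochastic methods are fully
    determined by ``random_state``.
    """

    def __init__(
        self,
        method: str = "rf",
        random_state: int = 0,
        max_pls_components: int = 5,
        n_trees: int = 500,
        cv_folds: int = 10,
        svr_epsilon: float = 0.01,
        svr_tol: float = 1e-3,
        hidden_layer_size: int = 200,
        epochs: int = 10,
        learning_rate: float = 0.005,
    ):
        self.method = method
        self.random_state = random_state
        self.max_pls_components = max_pls_components
        self.n_trees = n_trees
        self.cv_folds = cv_folds
        self.svr_epsilon = svr_epsilon
        self.svr_tol = svr_tol
        self.hidden_layer_size = hidden_layer_size
        self.epochs = epochs
        self.learning_rate = learning_rate

    def _make_estimator(self, n_features: int, n_train: int):
        if self.method == "plsr":
            # component count resolved in fit() by leave-one-out CV
            return PLSRegression(n_components=1, scale=False)
        if self.method == "lasso":
            return LassoCV(
                cv=min(self.cv_folds, n_train),
                random_state=self.random_state,
                max_iter=20000,
            )
        if self.method == "rf":
            return RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features=1.0 / 3.0,
                random_state=self.random_state,
                n_jobs=1,
            )
        if self.method == "svr":
            return SVR(
                kernel="rbf",
                gamma="auto",  # 1 / n_features
                epsilon=self.svr_epsilon,
                tol=self.svr_tol,
            )
        if self.method == "mlp":
            return MLPRegressor(
                hidden_layer_sizes=(self.hidden_layer_size, self.hidden_layer_size),
                solver="sgd",
                learning_rate="constant",
                learning_rate_init=self.learning_rate,
                max_iter=self.epochs,
                momentum=0.9,
                random_state=self.random_state,
            )
        raise ConfigurationError(f"unknown method {self.method!r}; valid: {METHODS}")

    def _select_pls_components(self, X: np.ndarray, y: np.ndarray) -> int:
        k_max = int(min(self.max_pls_components, X.shape[1], X.shape[0] - 1))
        best_k, best_err = 1, np.inf
        loo = LeaveOneOut()
        for k in range(1, k_max + 1):
            err = 0.0
            model = PLSRegression(n_components=k, scale=False)
            for tr, te in loo.split(X):
                m = clone(model).fit(X[tr], y[tr])
                err += float((m.predict(X[te]).ravel()[0] - y[te][0]) ** 2)
            if err < best_err - 1e-12:
                best_err, best_k = err, k
        return best_k

    def fit(self, X, y):
        Xv = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if Xv.ndim != 2 or Xv.shape[1] == 0:
            raise ModelError("feature matrix must be 2-D with at least one column")
        if Xv.shape[0] != y.shape[0]:
            raise ModelError("X and y row counts differ")
        if np.ptp(y) == 0:
            raise ModelError("degenerate target: zero variance")
        self.n_features_in_ = Xv.shape[1]

        scaler = StandardScaler()
        Xs = scaler.fit_transform(Xv)
        # the response is standardized internally for optimization (as the
        # reference SVM / deep-learning tools do) and predictions are
        # back-transformed; scale-free fits are unaffected
        self.y_mean_ = float(y.mean())
        self.y_scale_ = float(y.std()) or 1.0
        ys = (y - self.y_mean_) / self.y_scale_
        if self.method == "plsr":
            self.selected_components_ = self._select_pls_components(Xs, ys)
            est = PLSRegression(n_components=self.selected_components_, scale=False)
        else:
            est = self._make_estimator(Xv.shape[1], Xv.shape[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xs, ys)
        self.model_ = Pipeline([("scale", scaler), ("model", est)])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        raw = np.asarray(self.model_.predict(np.asarray(X, dtype=float))).ravel()
        return self.y_mean_ + self.y_scale_ * raw

    def score(self, X, y, sample_weight=None) -> float:
        return regression_metrics(y, self.predict(X))["r2"]


def fit_predict(
    spec: ModelSpec | str,
    train: pd.DataFrame,
    validation: pd.DataFrame,
    feature_cols: list[str],
    target: str,
    feature_set: str = "all",
) -> ModelResult:
    """Fit one method on a train frame and evaluate on train + validation."""
    if isinstance(spec, str):
        spec = ModelSpec(method=spec)
    reg = YieldRegressor(method=spec.method, random_state=spec.seed, **spec.params)
    X_tr = train[feature_cols].to_numpy(dtype=float)
    y_tr = train[target].to_numpy(dtype=float)
    X_va = validation[feature_cols].to_numpy(dtype=float)
    y_va = validation[target].to_numpy(dtype=float)
    reg.fit(X_tr, y_tr)
    pred_tr = reg.predict(X_tr)
    pred_va = reg.predict(X_va)
    preds = pd.concat(
        [
            pd.DataFrame(
                {"plot_id": train.index, "split": "train", "observed": y_tr, "predicted": pred_tr}
            ),
            pd.DataFrame(
                {
                    "plot_id": validation.index,
                    "split": "validation",
                    "observed": y_va,
                    "predicted": pred_va,
                }
            ),
        ],
        ignore_index=True,
    )
    return ModelResult(
        method=spec.method,
        feature_set=feature_set,
        target=target,
        n_features=len(feature_cols),
        train_metrics=regression_metrics(y_tr, pred_tr),
        validation_metrics=regression_metrics(y_va, pred_va),
        predictions=preds,
    )
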