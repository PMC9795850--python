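"""Feature screening: shadow-feature (Boruta-style) selection and
one-class-SVM outlier rejection.

The shadow screen augments the candidate matrix with a row-permuted copy of
every column, fits a random forest (bagged trees with one-third of the
features tried per split), and scores each column by classic out-of-bag
permutation importance (mean increase in squared error when the column is
permuted on each tree's out-of-bag rows).  Over ``n_runs`` independent
rounds, a feature that ranks below the *best shadow* importance in at least
``cutoff`` rounds (default 80 of 100) is removed; everything else is kept.
Lodging and canopy cover are excluded from screening at the pipeline level
and always kept.

Row-wise outlier rejection uses a radial-basis one-class SVM (gamma 0.001,
support-vector fraction lower bound nu = 0.03, tolerance 1e-3) on
standardized features; rows outside the learned boundary are dropped before
the train/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin
from sklearn.ensemble import BaggingRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, ScreeningError


@dataclass(frozen=True)
class OutlierConfig:
    """One-class-SVM configuration (radial basis kernel)."""

    gamma: float = 0.001
    nu: float = 0.03  # lower bound on the support-vector fraction
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 < self.nu < 1):
            raise ConfigurationError("nu must lie in (0, 1)")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")


@dataclass
class ScreeningReport:
    """Per-feature outcome of the shadow screen."""

    frame: pd.DataFrame  # feature, times_below_best_shadow, mean_rank, decision
    n_runs: int
    cutoff: int
    excluded: tuple[str, ...] = field(default_factory=tuple)  # kept without screening

    @property
    def removed(self) -> list[str]:
        return list(self.frame.index[self.frame["decision"] == "remove"])

    @property
    def kept(self) -> list[str]:
        return list(self.frame.index[self.frame["decision"] == "keep"]) + list(self.excluded)


def shadow_augment(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Append one independently row-permuted (shadow) copy of every column.

    Each shadow preserves its source column's marginal distribution exactly
    (same multiset of values) while destroying its association with anything
    else.  Column count doubles; shadows sit after the real columns.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ScreeningError("need a 2-D matrix with at least 2 rows")
    n, p = X.shape
    shadows = np.empty_like(X)
    for j in range(p):
        shadows[:, j] = X[rng.permutation(n), j]
    return np.hstack([X, shadows])


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int) -> BaggingRegressor:
    # bagged trees trying p/3 features per split == regression random forest
    # (node size 5, the regression-forest convention); BaggingRegressor
    # exposes the in-bag indices needed for OOB importance
    forest = BaggingRegressor(
        estimator=DecisionTreeRegressor(max_features=1.0 / 3.0, min_samples_leaf=5),
        n_estimators=n_trees,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def oob_permutation_importance(
    forest: BaggingRegressor,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    scale: bool = True,
) -> np.ndarray:
    """Per-column out-of-bag permutation importance.

    For each tree, the column is permuted on the tree's out-of-bag rows and
    the increase of the tree's OOB mean squared error recorded.  With
    ``scale=True`` (the random-forest convention for the mean-decrease-in-
    accuracy measure) the per-tree increases are normalized to a Z score:
    mean divided by its standard error over trees.  Columns the forest never
    uses (including constants) score exactly zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    increments = []
    all_rows = np.arange(n)
    for est, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(all_rows, samples, assume_unique=False)
        m = oob.size
        if m < 2:
            continue
        Xo = X[oob]
        yo = y[oob]
        perm = rng.permutation(m)
        big = np.empty(((p + 1) * m, p))
        stacked = big.reshape(p + 1, m, p)
        stacked[:] = Xo[None, :, :]
        for j in range(p):
            stacked[j + 1, :, j] = Xo[perm, j]
        preds = est.predict(big).reshape(p + 1, m)
        base = np.mean((preds[0] - yo) ** 2)
        mses = np.mean((preds[1:] - yo[None, :]) ** 2, axis=1)
        increments.append(mses - base)
    if not increments:
        raise ScreeningError("no tree had enough out-of-bag rows")
    inc = np.asarray(increments)
    mean = inc.mean(axis=0)
    if not scale:
        return mean
    se = inc.std(axis=0, ddof=0) / np.sqrt(inc.shape[0])
    return np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)


def rf_importance(
    X_aug: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forest importance of every column of an (augmented) matrix."""
    X_aug = np.asarray(X_aug, dtype=float)
    y = np.asarray(y, dtype=float)
    if X_aug.shape[0] != y.shape[0]:
        raise ScreeningError("X and y row counts differ")
    if np.ptp(y) == 0:
        raise ScreeningError("constant target: importance undefined")
    rng = rng or np.random.default_rng()
    forest = _fit_forest(X_aug, y, n_trees, int(rng.integers(2**31)))
    return oob_permutation_importance(forest, X_aug, y, rng)


class BorutaScreener(BaseEstimator, TransformerMixin):
    """All-relevant shadow-feature screen with the 80-of-100 removal rule.

    Parameters
    ----------
    n_runs : independent shadow-augment + importance rounds (default 100).
    cutoff : a feature ranking below the best shadow in at least this many
        rounds is removed (default 80).  Must not exceed ``n_runs``.
    n_trees : trees per forest round.
    random_state : master seed; every round derives its own stream.

    Attributes (after ``fit``)
    --------------------------
    importance_history_ : (n_runs, p) importance of each real feature per round.
    times_below_shadow_ : rounds in which each feature scored strictly below
        the round's best shadow importance.
    support_ : boolean keep-mask.
    decision_ : "keep" / "remove" per feature.
    ranking_ : average importance rank (1 = most important).
    report_ : :class:`ScreeningReport`.
    """

    def __init__(
        self,
        n_runs: int = 100,
        cutoff: int = 80,
        n_trees: int = 100,
        random_state: int | None = None,
    ):
        self.n_runs = n_runs
        self.cutoff = cutoff
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_runs < self.cutoff:
            raise ConfigurationError(
                f"n_runs ({self.n_runs}) must be >= cutoff ({self.cutoff})"
            )
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xv.shape[1])]
        y = np.asarray(y, dtype=float)
        if Xv.ndim != 2 or Xv.shape[0] < 2:
            raise ScreeningError("need at least 2 rows to screen")
        if Xv.shape[0] != y.shape[0]:
            raise ScreeningError("X and y row counts differ")
        n, p = Xv.shape

        master = np.random.default_rng(
            self.random_state if self.random_state is not None else None
        )
        seeds = master.integers(2**31, size=self.n_runs)
        history = np.empty((self.n_runs, p))
        below = np.zeros(p, dtype=int)
        ranks = np.zeros(p)
        for run in range(self.n_runs):
            rng = np.random.default_rng(int(seeds[run]))
            X_aug = shadow_augment(Xv, rng)
            imp = rf_importance(X_aug, y, n_trees=self.n_trees, rng=rng)
            real, shadow = imp[:p], imp[p:]
            best_shadow = shadow.max()
            below += real < best_shadow
            history[run] = real
            order = np.argsort(-real, kind="stable")
            rk = np.empty(p)
            rk[order] = np.arange(1, p + 1)
            ranks += rk

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        self.importance_history_ = history
        self.times_below_shadow_ = below
        self.ranking_ = ranks / self.n_runs
        self.support_ = below < self.cutoff
        self.decision_ = np.where(self.support_, "keep", "remove")
        self.report_ = ScreeningReport(
            frame=pd.DataFrame(
                {
                    "times_below_best_shadow": below,
                    "mean_rank": self.ranking_,
                    "mean_importance": history.mean(axis=0),
                    "decision": self.decision_,
                },
                index=pd.Index(names, name="feature"),
            ),
            n_runs=self.n_runs,
            cutoff=self.cutoff,
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


def boruta_rank_runs(
    X,
    y,
    n_runs: int = 100,
    cutoff: int = 80,
    n_trees: int = 100,
    random_state: int | None = None,
) -> ScreeningReport:
    """Functional wrapper: run the shadow screen and return its report."""
    screener = BorutaScreener(
        n_runs=n_runs, cutoff=cutoff, n_trees=n_trees, random_state=random_state
    )
    screener.fit(X, y)
    return screener.report_


class OneClassOutlierFilter(BaseEstimator, OutlierMixin):
    """Standardize-then-one-class-SVM outlier detector.

    A radial-basis one-class SVM wraps the bulk of the standardized feature
    cloud in a minimal boundary; rows with negative decision function are
    flagged.  With the default nu = 0.03 the flagged fraction on clean data
    stays near (and is bounded below by roughly) 3%.
    """

    def __init__(self, gamma: float = 0.001, nu: float = 0.03, tol: float = 1e-3):
        self.gamma = gamma
        self.nu = nu
        self.tol = tol

    def fit(self, X, y=None):
        OutlierConfig(gamma=self.gamma, nu=self.nu, tol=self.tol)  # validate
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim != 2 or Xv.shape[0] < 10:
            raise ScreeningError("need at least 10 rows to identify a boundary")
        self.scaler_ = StandardScaler().fit(Xv)
        self.svm_ = OneClassSVM(kernel="rbf", gamma=self.gamma, nu=self.nu, tol=self.tol)
        self.svm_.fit(self.scaler_.transform(Xv))
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        return self.svm_.decision_function(self.scaler_.transform(np.asarray(X, dtype=float)))

    def predict(self, X) -> np.ndarray:
        """+1 for inliers, -1 for outliers (sklearn convention)."""
        check_is_fitted(self, "svm_")
        return self.svm_.predict(self.scaler_.transform(np.asarray(X, dtype=float)))

    def inlier_mask(self, X) -> np.ndarray:
        return self.predict(X) == 1


def ocsvm_filter(X, config: OutlierConfig = OutlierConfig()) -> np.ndarray:
    """Boolean inlier mask for the rows of a feature matrix."""
    f = OneClassOutlierFilter(gamma=config.gamma, nu=config.nu, tol=config.tol)
    f.fit(X)
    return f.inlier_mask(X)
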