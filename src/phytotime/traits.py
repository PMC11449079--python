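"""Trait prediction from standardized expression with tiered LOOCV elastic nets.

Continuous traits (biomass, leaf area) and bolting status are predicted from
z-scored expression with elastic-net-regularized linear and logistic models.
The scheme is tiered: an outer leave-one-out loop measures generalisation,
and within each outer training set an inner 5-fold cross-validation picks the
penalty strength and l1_ratio. Because l1_ratio controls variable selection,
one value (the mode across outer folds) is then fixed and every fold is
refitted at it, so coefficient vectors are comparable across folds; a gene's
consensus effect is its median coefficient across folds.

Standardization statistics are recomputed inside each outer training fold by
default, so the held-out sample never leaks into its own prediction; a
``standardize='global'`` compatibility mode scales once on the full matrix.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, ClassifierMixin
from sklearn.linear_model import ElasticNetCV, LogisticRegressionCV
from sklearn.metrics import confusion_matrix, mean_squared_error, r2_score
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "standardize_features",
    "fix_l1_ratio",
    "consensus_predictors",
    "ElasticNetLOOCV",
    "LogisticLOOCV",
    "loocv_elastic_net",
    "loocv_logistic",
]

L1_GRID = (0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0)


def standardize_features(expr: pd.DataFrame, regulator_set=None) -> pd.DataFrame:
    """Samples x genes z-scored feature matrix from a genes x samples TPM
    matrix, optionally restricted to a regulator gene set.

    Zero-variance genes are dropped with a warning; an empty regulator match
    is an error (it almost always means mismatched identifiers).
    """
    if regulator_set is not None:
        found = expr.index.intersection(pd.Index(list(regulator_set)))
        if len(found) == 0:
            raise ValueError("no requested regulator genes found in the matrix")
        expr = expr.loc[found]
    X = expr.T
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} zero-variance gene(s)", stacklevel=2)
        X = X.loc[:, ~const]
        sd = sd[~const]
    return (X - X.mean(axis=0)) / sd


def fix_l1_ratio(per_fold_choices) -> float:
    """Mode of the per-fold l1_ratio selections; ties go to the smaller
    (more ridge-like, hence stabler) value."""
    choices = list(per_fold_choices)
    if not choices:
        raise ValueError("empty choice list")
    counts = Counter(choices)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def consensus_predictors(coef_per_fold: pd.DataFrame) -> pd.DataFrame:
    """Genes with nonzero median coefficient across folds, sorted by |median|.

    ``coef_per_fold`` is folds x genes. The median is a conservative
    consensus: a gene zeroed out in more than half the folds is excluded.
    """
    med = coef_per_fold.median(axis=0)
    out = pd.DataFrame({"median_coef": med, "sign": np.sign(med)})
    out = out[out["median_coef"] != 0]
    return out.reindex(out["median_coef"].abs().sort_values(ascending=False).index)


class _TieredLOOCV(BaseEstimator):
    """Shared outer-LOOCV machinery; subclasses supply the inner learner."""

    def __init__(self, l1_grid=L1_GRID, n_inner: int = 5, standardize: str = "per-fold",
                 random_state: int | None = None):
        self.l1_grid = l1_grid
        self.n_inner = n_inner
        self.standardize = standardize
        self.random_state = random_state

    def _scale_pair(self, X_train: np.ndarray, X_test: np.ndarray):
        if self.standardize == "global":
            return X_train, X_test
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (X_train - mu) / sd, (X_test - mu) / sd

    def _loop(self, X: pd.DataFrame, y: np.ndarray):
        X = pd.DataFrame(X)
        if self.standardize == "global":
            vals = X.to_numpy(dtype=float)
            mu, sd = vals.mean(axis=0), vals.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            X = pd.DataFrame((vals - mu) / sd, index=X.index, columns=X.columns)
        n = len(X)
        preds = np.empty(n, dtype=float)
        chosen_l1 = []
        first_pass = []
        Xv = X.to_numpy(dtype=float)
        for i in range(n):
            tr = np.arange(n) != i
            Xtr, Xte = self._scale_pair(Xv[tr], Xv[~tr])
            model = self._fit_inner(Xtr, y[tr], l1_ratios=list(self.l1_grid))
            first_pass.append(model)
            chosen_l1.append(self._chosen_l1(model))
            preds[i] = self._predict_one(model, Xte)
        fixed = fix_l1_ratio(chosen_l1)
        coefs = np.empty((n, X.shape[1]), dtype=float)
        final_preds = np.empty(n, dtype=float)
        for i in range(n):
            tr = np.arange(n) != i
            Xtr, Xte = self._scale_pair(Xv[tr], Xv[~tr])
            model = self._fit_inner(Xtr, y[tr], l1_ratios=[fixed])
            coefs[i] = np.ravel(model.coef_)
            final_preds[i] = self._predict_one(model, Xte)
        self.l1_ratio_ = fixed
        self.l1_choices_ = chosen_l1
        self.coef_per_fold_ = pd.DataFrame(coefs, index=X.index, columns=X.columns)
        self.predictions_ = pd.Series(final_preds, index=X.index, name="predicted")
        self.first_pass_predictions_ = pd.Series(preds, index=X.index)
        self.median_coef_ = self.coef_per_fold_.median(axis=0)
        return self


class ElasticNetLOOCV(_TieredLOOCV, RegressorMixin):
    """Tiered LOOCV elastic net for continuous traits.

    Attributes after ``fit``: ``predictions_`` (assembled held-out
    predictions), ``r2_``, ``rmse_``, ``l1_ratio_`` (fixed mode value),
    ``coef_per_fold_``, ``median_coef_``.
    """

    def _fit_inner(self, X, y, l1_ratios):
        cv = KFold(self.n_inner, shuffle=True, random_state=self.random_state)
        return ElasticNetCV(l1_ratio=l1_ratios, cv=cv, max_iter=5000).fit(X, y)

    @staticmethod
    def _chosen_l1(model):
        return float(model.l1_ratio_)

    @staticmethod
    def _predict_one(model, Xte):
        return float(model.predict(Xte)[0])

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if len(y) < 10:
            raise ValueError("need at least 10 samples for the tiered LOOCV scheme")
        if not np.isfinite(y).all():
            raise ValueError("y must be finite")
        if np.ptp(y) == 0:
            raise ValueError("constant trait cannot be modelled")
        self._loop(X, y)
        self.r2_ = float(r2_score(y, self.predictions_))
        self.rmse_ = float(np.sqrt(mean_squared_error(y, self.predictions_)))
        return self

    def predict(self, X=None):
        return self.predictions_.to_numpy()


class LogisticLOOCV(_TieredLOOCV, ClassifierMixin):
    """Tiered LOOCV elastic-net logistic regression for bolting status.

    Inner stratified 5-fold CV searches 10 C values and the l1_ratio grid;
    attributes after ``fit``: ``accuracy_``, ``confusion_matrix_`` (2x2),
    ``predictions_``, ``l1_ratio_``, ``coef_per_fold_``.
    """

    def __init__(self, l1_grid=L1_GRID, n_inner: int = 5, n_cs: int = 10,
                 standardize: str = "per-fold", random_state: int | None = None):
        super().__init__(l1_grid=l1_grid, n_inner=n_inner, standardize=standardize,
                         random_state=random_state)
        self.n_cs = n_cs

    def _fit_inner(self, X, y, l1_ratios):
        cv = StratifiedKFold(self.n_inner, shuffle=True, random_state=self.random_state)
        return LogisticRegressionCV(
            Cs=self.n_cs, cv=cv, penalty="elasticnet", solver="saga",
            l1_ratios=l1_ratios, max_iter=5000, tol=1e-3,
        ).fit(X, y)

    @staticmethod
    def _chosen_l1(model):
        return float(np.ravel(model.l1_ratio_)[0])

    @staticmethod
    def _predict_one(model, Xte):
        return float(model.predict(Xte)[0])

    def fit(self, X, y):
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        self._loop(pd.DataFrame(X), y)
        pred = self.predictions_.to_numpy().astype(int)
        self.accuracy_ = float((pred == y).mean())
        self.confusion_matrix_ = confusion_matrix(y, pred, labels=[0, 1])
        return self

    def predict(self, X=None):
        return self.predictions_.to_numpy().astype(int)


def loocv_elastic_net(X, y, l1_grid=L1_GRID, random_state: int | None = None) -> ElasticNetLOOCV:
    """Functional wrapper over :class:`ElasticNetLOOCV`."""
    return ElasticNetLOOCV(l1_grid=l1_grid, random_state=random_state).fit(X, y)


def loocv_logistic(X, y, n_cs: int = 10, random_state: int | None = None) -> LogisticLOOCV:
    """Functional wrapper over :class:`LogisticLOOCV`."""
    return LogisticLOOCV(n_cs=n_cs, random_state=random_state).fit(X, y)
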