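"""Two-step normalization: MAD-based feature filtering and cohort scaling.

The training cohort is filtered by median absolute deviation (features with
MAD at or below a threshold are dropped; a top-k-by-MAD option exists),
then scaled per feature (robust: median/IQR, or standard: mean/SD).  The
statistics fitted on the training cohort are reused verbatim on validation
cohorts.  A final per-feature min-max squash into ``[eps, 1-eps]`` prepares
the matrix for the autoencoder's logistic reconstruction loss.

Estimators follow the scikit-learn convention (samples as rows); the
module-level functions operate on feature-by-sample DataFrames as stored
on disk and are thin wrappers over the estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ContractError


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[str(i) for i in range(X.shape[1])])


class MADFilter(BaseEstimator, TransformerMixin):
    """Drop features whose median absolute deviation is not above ``min_mad``.

    Parameters
    ----------
    min_mad : float, default 0.0
        Strict lower bound on the (unscaled) MAD; with the default, exactly
        the constant features are removed.
    top_k : int or None
        If given, keep only the ``top_k`` surviving features with the
        largest MAD (original order preserved).
    """

    def __init__(self, min_mad: float = 0.0, top_k: int | None = None):
        self.min_mad = min_mad
        self.top_k = top_k

    def fit(self, X, y=None):
        if self.min_mad < 0:
            raise ContractError("min_mad must be >= 0")
        X = _as_frame(X)
        v = X.to_numpy(dtype=float)
        med = np.median(v, axis=0)
        self.mad_ = np.median(np.abs(v - med), axis=0)
        support = self.mad_ > self.min_mad
        if self.top_k is not None and support.sum() > self.top_k:
            kept = np.argsort(-self.mad_, kind="stable")
            kept = [i for i in kept if support[i]][: self.top_k]
            support = np.zeros_like(support)
            support[kept] = True
        if not support.any():
            raise ContractError(
                f"MAD filter removed every feature (min_mad={self.min_mad}); "
                "lower the threshold"
            )
        self.support_ = support
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = _as_frame(X)
        return X.loc[:, self.feature_names_in_[self.support_]]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


class CohortScaler(BaseEstimator, TransformerMixin):
    """Per-feature centering/scaling with training statistics reused downstream.

    ``mode="robust"`` stores median and interquartile range (linear
    interpolation quantiles); ``mode="standard"`` stores mean and population
    standard deviation.  A zero spread is an error naming the feature —
    run :class:`MADFilter` first.
    """

    def __init__(self, mode: str = "robust"):
        self.mode = mode

    def fit(self, X, y=None):
        if self.mode not in ("robust", "standard"):
            raise ContractError(f"unknown scaler mode {self.mode!r}")
        X = _as_frame(X)
        v = X.to_numpy(dtype=float)
        if self.mode == "robust":
            center = np.median(v, axis=0)
            q75, q25 = np.percentile(v, [75, 25], axis=0)
            spread = q75 - q25
        else:
            center = v.mean(axis=0)
            spread = v.std(axis=0, ddof=0)
        zero = spread <= 0
        if zero.any():
            bad = np.asarray(X.columns)[zero].tolist()[:10]
            raise ContractError(
                f"zero spread under mode {self.mode!r} for feature(s) {bad}; "
                "apply a MAD filter first"
            )
        self.center_ = center
        self.spread_ = spread
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "center_")
        X = _as_frame(X)
        missing = [f for f in self.feature_names_in_ if f not in X.columns]
        if missing:
            raise ContractError(f"matrix is missing scaler feature(s): {missing[:10]}")
        X = X.loc[:, self.feature_names_in_]
        return (X - self.center_) / self.spread_


class UnitSquasher(BaseEstimator, TransformerMixin):
    """Per-feature min-max map into ``[epsilon, 1-epsilon]``.

    Constant features map to 0.5.  When applied to new data, the training
    minima/maxima are reused and the result is clipped back into the target
    interval, so the logistic reconstruction loss stays well-defined.
    """

    def __init__(self, epsilon: float = 0.01):
        self.epsilon = epsilon

    def fit(self, X, y=None):
        if not 0 < self.epsilon < 0.5:
            raise ContractError("epsilon must lie in (0, 0.5)")
        X = _as_frame(X)
        v = X.to_numpy(dtype=float)
        self.min_ = v.min(axis=0)
        self.max_ = v.max(axis=0)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "min_")
        X = _as_frame(X).loc[:, self.feature_names_in_]
        rng = self.max_ - self.min_
        eps = self.epsilon
        v = X.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = eps + (1 - 2 * eps) * (v - self.min_) / rng
        out = np.where(rng > 0, out, 0.5)
        return pd.DataFrame(out, index=X.index, columns=X.columns).clip(eps, 1 - eps)


# ---------------------------------------------------------------------------
# functional wrappers on feature-by-sample matrices


def mad_filter(m: pd.DataFrame, min_mad: float = 0.0, top_k: int | None = None) -> pd.DataFrame:
    """Retain features (rows) whose MAD strictly exceeds ``min_mad``."""
    return MADFilter(min_mad=min_mad, top_k=top_k).fit_transform(m.T).T


def fit_scaler(train: pd.DataFrame, mode: str = "robust") -> CohortScaler:
    """Fit a per-feature scaler on a feature-by-sample training matrix."""
    return CohortScaler(mode=mode).fit(train.T)


def apply_scaler(m: pd.DataFrame, scaler: CohortScaler) -> pd.DataFrame:
    """Apply a fitted scaler to a feature-by-sample matrix."""
    return scaler.transform(m.T).T


def squash_to_unit(m: pd.DataFrame, epsilon: float = 0.01) -> pd.DataFrame:
    """Per-feature min-max squash of a feature-by-sample matrix."""
    return UnitSquasher(epsilon=epsilon).fit_transform(m.T).T
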