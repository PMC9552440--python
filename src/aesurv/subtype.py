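"""Survival screening of latent features and K-means subtype discovery.

The screen fits a univariate Cox proportional-hazards model to every
latent feature (Newton-Raphson on the Breslow partial likelihood,
vectorized across features) and keeps features with Wald p < alpha.
K-means is then run over a candidate range of cluster numbers; the
Calinski-Harabasz score picks k (silhouette reported, used only for
ties, then smaller k).  Clusters are finally renamed G1..Gk in decreasing
order of median observed survival, so the worst-prognosis cluster is
always the last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.utils.validation import check_is_fitted

from .exceptions import ContractError


def univariate_cox(
    X,
    time,
    event,
    alpha: float = 0.05,
    tol: float = 1e-7,
    max_iter: int = 60,
    feature_names=None,
) -> pd.DataFrame:
    """Univariate Cox-PH fit per feature (Breslow ties, Wald test).

    Features are standardized internally for conditioning; reported
    coefficients are on the original scale.  Newton iterations are capped;
    a feature whose fit degenerates (constant values, vanishing
    information) is flagged unselected with a diagnostic rather than
    raising.

    Returns a DataFrame with columns ``feature, coef, se, z, p_value,
    selected, converged, note``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, F = X.shape
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    if t.shape[0] != n or d.shape[0] != n:
        raise ContractError("time/event length does not match X")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(F)]

    order = np.argsort(t, kind="stable")
    ts, ds, Xs = t[order], d[order], X[order]
    uniq, first = np.unique(ts, return_index=True)
    # per unique time: number of events and sum of x over events
    grp = np.searchsorted(uniq, ts)
    d_k = np.bincount(grp, weights=ds, minlength=len(uniq))
    has_events = d_k > 0

    mu = Xs.mean(axis=0)
    sd = Xs.std(axis=0, ddof=0)
    valid = sd > 0
    Z = np.zeros_like(Xs)
    Z[:, valid] = (Xs[:, valid] - mu[valid]) / sd[valid]
    s_k = np.zeros((len(uniq), F))
    np.add.at(s_k, grp, Z * ds[:, None])

    beta = np.zeros(F)
    converged = np.zeros(F, dtype=bool)
    info = np.full(F, np.nan)
    active = valid.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.clip(Z[:, active] * beta[active], -300, 300)
        E = np.exp(eta)
        XE = Z[:, active] * E
        X2E = Z[:, active] * XE
        R0 = np.cumsum(E[::-1], axis=0)[::-1][first]
        R1 = np.cumsum(XE[::-1], axis=0)[::-1][first]
        R2 = np.cumsum(X2E[::-1], axis=0)[::-1][first]
        m = R1 / R0
        grad = (s_k[:, active] - d_k[:, None] * m)[has_events].sum(axis=0)
        I = (d_k[:, None] * (R2 / R0 - m * m))[has_events].sum(axis=0)
        ok = np.isfinite(grad) & np.isfinite(I) & (I > 1e-12)
        step = np.where(ok, grad / np.where(I > 1e-12, I, 1.0), 0.0)
        step = np.clip(step, -2.5, 2.5)
        beta[active] += np.where(ok, step, 0.0)
        info[active] = np.where(ok, I, np.nan)
        idx = np.flatnonzero(active)
        done = (np.abs(step) < tol) | ~ok
        converged[idx[done & ok]] = True
        active[idx[done]] = False

    se_std = np.where(info > 0, 1.0 / np.sqrt(np.where(info > 0, info, 1.0)), np.nan)
    z = beta / se_std
    p = 2.0 * stats.norm.sf(np.abs(z))
    coef = np.where(valid, beta / np.where(valid, sd, 1.0), np.nan)
    se = np.where(valid, se_std / np.where(valid, sd, 1.0), np.nan)

    usable = valid & np.isfinite(p)
    note = np.where(
        ~valid, "constant feature",
        np.where(~np.isfinite(p), "degenerate fit",
                 np.where(converged, "", "newton iteration cap reached")),
    )
    selected = usable & (p < alpha)
    return pd.DataFrame(
        {
            "feature": feature_names,
            "coef": coef,
            "se": se,
            "z": z,
            "p_value": np.where(usable, p, np.nan),
            "selected": selected,
            "converged": converged,
            "note": note,
        }
    )


def cox_screen(latent: pd.DataFrame, clinical: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Screen a samples-by-features latent matrix against survival.

    ``latent`` rows and ``clinical`` rows must refer to the same samples.
    """
    if not latent.index.equals(clinical.index):
        if set(latent.index) != set(clinical.index):
            raise ContractError("latent and clinical sample ids differ")
        clinical = clinical.loc[latent.index]
    return univariate_cox(
        latent.to_numpy(dtype=float),
        clinical["time"].to_numpy(),
        clinical["event"].to_numpy(),
        alpha=alpha,
        feature_names=list(latent.columns),
    )


class CoxFeatureScreen(BaseEstimator, TransformerMixin):
    """Transformer keeping features univariately associated with survival.

    ``y`` in :meth:`fit` is a ``(time, event)`` tuple of arrays or a
    2-column array.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    @staticmethod
    def _split_y(y):
        if isinstance(y, tuple):
            return np.asarray(y[0], float), np.asarray(y[1], float)
        y = np.asarray(y, dtype=float)
        return y[:, 0], y[:, 1]

    def fit(self, X, y):
        time, event = self._split_y(y)
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        self.screen_ = univariate_cox(
            np.asarray(X, dtype=float), time, event, alpha=self.alpha, feature_names=names
        )
        self.support_ = self.screen_["selected"].to_numpy()
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if not self.support_.any():
            raise ContractError(
                "no survival-associated feature at this alpha; relax alpha"
            )
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


@dataclass
class ClusterSelection:
    chosen_k: int
    labels: np.ndarray
    scores: pd.DataFrame  # index k, columns calinski_harabasz / silhouette


class KMeansSubtyper(BaseEstimator):
    """K-means over k = k_min..k_max with score-based model selection."""

    def __init__(self, k_min: int = 2, k_max: int = 6, n_init: int = 10, random_state: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ContractError("X must be 2-D with at least one selected feature")
        if self.k_min < 2:
            raise ContractError("k_min must be >= 2")
        if X.shape[0] <= self.k_max:
            raise ContractError("need more samples than k_max")
        rows, labels_by_k = [], {}
        for k in range(self.k_min, self.k_max + 1):
            km = KMeans(
                n_clusters=k, n_init=self.n_init, random_state=self.random_state
            ).fit(X)
            lab = km.labels_
            labels_by_k[k] = lab
            rows.append(
                {
                    "k": k,
                    "calinski_harabasz": calinski_harabasz_score(X, lab),
                    "silhouette": silhouette_score(X, lab),
                }
            )
        scores = pd.DataFrame(rows).set_index("k")
        # primary: CH; ties: larger silhouette, then smaller k
        ranked = scores.sort_values(
            ["calinski_harabasz", "silhouette"], ascending=[False, False], kind="stable"
        )
        best = ranked[
            (ranked["calinski_harabasz"] == ranked["calinski_harabasz"].iloc[0])
            & (ranked["silhouette"] == ranked["silhouette"].iloc[0])
        ]
        self.chosen_k_ = int(best.index.min())
        self.labels_ = labels_by_k[self.chosen_k_]
        self.scores_ = scores
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @property
    def selection_(self) -> ClusterSelection:
        check_is_fitted(self, "labels_")
        return ClusterSelection(self.chosen_k_, self.labels_, self.scores_)


def kmeans_select(
    latent_selected: pd.DataFrame, k_min: int = 2, k_max: int = 6, seed: int = 0
) -> ClusterSelection:
    """Functional wrapper over :class:`KMeansSubtyper` on a samples-by-features frame."""
    sub = KMeansSubtyper(k_min=k_min, k_max=k_max, random_state=seed)
    sub.fit(latent_selected.to_numpy(dtype=float))
    return sub.selection_


@dataclass
class SubtypeResult:
    labels: pd.Series  # sample id -> "G1".."Gk"
    selection: ClusterSelection | None = None
    ordering: str = "median survival descending (G1 best prognosis)"


def name_subtypes(
    selection: ClusterSelection | np.ndarray, clinical: pd.DataFrame
) -> SubtypeResult:
    """Rename clusters G1..Gk by decreasing median observed survival.

    Ties are broken by larger mean survival, then by cluster size
    (descending).  Pure renaming: the partition is unchanged.
    """
    sel = selection if isinstance(selection, ClusterSelection) else None
    raw = np.asarray(selection.labels if sel else selection)
    if len(raw) != len(clinical):
        raise ContractError("labels and clinical table have different lengths")
    t = clinical["time"].to_numpy(dtype=float)
    stats_rows = []
    for c in np.unique(raw):
        mask = raw == c
        if not mask.any():
            raise ContractError(f"cluster {c} is empty")
        stats_rows.append(
            (c, np.median(t[mask]), t[mask].mean(), int(mask.sum()))
        )
    ordered = sorted(stats_rows, key=lambda r: (-r[1], -r[2], -r[3]))
    mapping = {c: f"G{i + 1}" for i, (c, *_rest) in enumerate(ordered)}
    labels = pd.Series([mapping[c] for c in raw], index=clinical.index, name="subtype")
    return SubtypeResult(labels=labels, selection=sel)
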