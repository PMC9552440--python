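"""Survival evaluation: concordance, Brier score, log-rank, covariate tests.

Harrell's concordance index is computed by explicit pair enumeration:
a pair is permissible when the strictly shorter observed time ended in an
event; ties in predicted risk count 1/2.  The Brier score is the binary
flavor — mean squared difference between the predicted event probability
and the observed event indicator over follow-up — with an optional
time-horizon variant.  The log-rank test and the multivariate Cox model
comparison delegate to lifelines.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .exceptions import ContractError


def concordance_index(time, event, risk) -> float:
    """Harrell's C over permissible pairs; higher risk should fail earlier."""
    t = np.asarray(time, dtype=float)
    d = np.asarray(event)
    r = np.asarray(risk, dtype=float)
    if not (len(t) == len(d) == len(r)):
        raise ContractError("time/event/risk lengths differ")
    permissible = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_perm = int(permissible.sum())
    if n_perm == 0:
        raise ContractError("no permissible pair (no events before another time)")
    concordant = permissible & (r[:, None] > r[None, :])
    tied = permissible & (r[:, None] == r[None, :])
    return float((concordant.sum() + 0.5 * tied.sum()) / n_perm)


def brier_score(event_probability, event) -> float:
    """Binary Brier score of predicted event probabilities."""
    p = np.asarray(event_probability, dtype=float)
    y = np.asarray(event, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ContractError("event probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def brier_score_at(event_probability, time, event, horizon: float) -> float:
    """Time-horizon Brier variant: events before ``horizon`` vs known
    survivors at ``horizon``; subjects censored before the horizon are
    ambiguous and dropped."""
    p = np.asarray(event_probability, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event)
    died = (t <= horizon) & (d == 1)
    survived = t > horizon
    keep = died | survived
    if not keep.any():
        raise ContractError("no unambiguous subject at this horizon")
    return brier_score(p[keep], died[keep].astype(float))


def logrank_test(labels, time, event) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p-value)."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ContractError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(
        np.asarray(time, dtype=float), labels, np.asarray(event)
    )
    return float(res.test_statistic), float(res.p_value)


P_FLOOR = 1e-300


def aggregate_folds(per_fold: pd.DataFrame) -> dict:
    """Mean/SD for C-index and Brier, geometric mean for log-rank p.

    Sample SD (n-1 denominator); a single fold has SD 0.
    """
    if len(per_fold) == 0:
        raise ContractError("no folds to aggregate")

    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    p = np.clip(per_fold["logrank_p"].to_numpy(dtype=float), P_FLOOR, 1.0)
    return {
        "n_folds": int(len(per_fold)),
        "c_index_mean": float(per_fold["c_index"].mean()),
        "c_index_sd": _sd(per_fold["c_index"]),
        "brier_mean": float(per_fold["brier"].mean()),
        "brier_sd": _sd(per_fold["brier"]),
        "logrank_p_geomean": float(np.exp(np.mean(np.log(p)))),
    }


def covariate_tests(
    labels: pd.Series, clinical: pd.DataFrame, covariates=None
) -> pd.DataFrame:
    """Between-subtype tests: Wilcoxon rank-sum for continuous covariates
    (Kruskal-Wallis beyond two subtypes), chi-square without continuity
    correction for categorical ones.  Entirely-missing covariates are
    skipped with a warning."""
    labels = labels.loc[clinical.index]
    groups = labels.unique()
    if len(groups) < 2:
        raise ContractError("need at least two subtypes")
    if covariates is None:
        covariates = [c for c in clinical.columns if c not in ("time", "event")]
    rows = []
    for cov in covariates:
        if cov not in clinical.columns or clinical[cov].isna().all():
            warnings.warn(f"covariate {cov!r} missing entirely; skipped")
            continue
        col = clinical[cov]
        if np.issubdtype(col.dtype, np.number):
            samples = [col[labels == g].dropna().to_numpy() for g in sorted(groups)]
            if len(groups) == 2:
                stat, p = stats.ranksums(samples[0], samples[1])
                tag = "wilcoxon"
            else:
                stat, p = stats.kruskal(*samples)
                tag = "kruskal"
        else:
            table = pd.crosstab(labels, col)
            if table.shape[1] < 2:
                stat, p, tag = 0.0, 1.0, "chi_square"
            else:
                stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
                tag = "chi_square"
        rows.append({"covariate": cov, "test": tag, "statistic": float(stat), "p_value": float(p)})
    return pd.DataFrame(rows)


def _design(clinical: pd.DataFrame, labels: pd.Series, covariates: list[str]) -> pd.DataFrame:
    df = clinical[["time", "event"]].copy()
    for cov in covariates:
        if cov == "subtype":
            src = labels.loc[clinical.index]
        elif cov in clinical.columns:
            src = clinical[cov]
        else:
            raise ContractError(f"unknown covariate {cov!r}")
        if np.issubdtype(np.asarray(src).dtype, np.number):
            df[cov] = src
        else:
            dummies = pd.get_dummies(src, prefix=cov, drop_first=True, dtype=float)
            df = pd.concat([df, dummies], axis=1)
    return df.dropna()


def cox_compare(
    clinical: pd.DataFrame, labels: pd.Series, covariate_sets: list[list[str]]
) -> pd.DataFrame:
    """Fit one multivariate Cox-PH model per covariate set (``"subtype"``
    refers to the discovered labels) and report the in-sample C-index.

    Non-convergence is flagged in the result rather than raised.
    """
    rows = []
    for covs in covariate_sets:
        name = "+".join(covs)
        df = _design(clinical, labels, covs)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter(penalizer=1e-6).fit(df, "time", "event")
            rows.append(
                {"model": name, "c_index": float(cph.concordance_index_),
                 "n": int(len(df)), "converged": True, "note": ""}
            )
        except ConvergenceError as exc:
            rows.append(
                {"model": name, "c_index": np.nan, "n": int(len(df)),
                 "converged": False, "note": str(exc)[:200]}
            )
    return pd.DataFrame(rows)
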