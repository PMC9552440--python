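"""Methylation-driven gene detection and gene-set over-representation.

A gene is methylation-driven when (1) its methylation level is negatively
correlated with its expression across all samples (Spearman r strictly
below ``r_threshold``, default -0.3) and (2) its methylation differs
between subtypes (Wilcoxon rank-sum p strictly below ``p_threshold``,
default 0.05).  Direction follows the sign of the methylation difference
in the poor-prognosis subtype: ``hypo_up`` = hypomethylated and
over-expressed in G2, ``hyper_down`` the reverse.

Over-representation of a query gene list against user-supplied GMT
collections uses the one-sided hypergeometric tail with Benjamini-
Hochberg adjustment; the universe defaults to the genes shared between
the expression and methylation matrices.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ContractError, ParseError


def _rankdata_rows(v: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, v)


def _direction(r: float, p: float, meth_diff_g2: float,
               r_threshold: float, p_threshold: float) -> str:
    """Strict-inequality driver rule; boundary values are not flagged."""
    if r < r_threshold and p < p_threshold:
        return "hypo_up" if meth_diff_g2 < 0 else "hyper_down"
    return "none"


def find_driver_genes(
    expr: pd.DataFrame,
    meth: pd.DataFrame,
    labels: pd.Series,
    r_threshold: float = -0.3,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per shared gene: Spearman(meth, expr) across all samples and a
    Wilcoxon rank-sum test on methylation between the best- and
    worst-prognosis subtypes.

    ``expr`` and ``meth`` are feature-by-sample with gene ids as index;
    their gene and sample intersections are used.  Genes constant in
    either omic are skipped with a warning.
    """
    genes = [g for g in expr.index if g in set(meth.index)]
    samples = [s for s in expr.columns if s in set(meth.columns)]
    if len(samples) < 3:
        raise ContractError("fewer than 3 shared samples between expr and meth")
    if not genes:
        raise ContractError("no shared gene ids between expr and meth")
    labels = labels.loc[samples]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ContractError("need at least two subtypes")
    g_best, g_worst = groups[0], groups[-1]
    in_best = (labels == g_best).to_numpy()
    in_worst = (labels == g_worst).to_numpy()

    E = expr.loc[genes, samples].to_numpy(dtype=float)
    M = meth.loc[genes, samples].to_numpy(dtype=float)
    const = (E.std(axis=1) == 0) | (M.std(axis=1) == 0)
    if const.any():
        warnings.warn(
            f"{int(const.sum())} gene(s) constant in one omic; correlation "
            "undefined, skipped"
        )
    # Spearman = Pearson on ranks, vectorized over genes
    rE = _rankdata_rows(E)
    rM = _rankdata_rows(M)
    rE = rE - rE.mean(axis=1, keepdims=True)
    rM = rM - rM.mean(axis=1, keepdims=True)
    denom = np.sqrt((rE * rE).sum(axis=1) * (rM * rM).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (rE * rM).sum(axis=1) / denom, np.nan)

    rows = []
    for i, gene in enumerate(genes):
        if const[i]:
            continue
        stat, p = stats.ranksums(M[i, in_best], M[i, in_worst])
        mm1, mm2 = M[i, in_best].mean(), M[i, in_worst].mean()
        me1, me2 = E[i, in_best].mean(), E[i, in_worst].mean()
        rows.append(
            {
                "gene": gene,
                "spearman_r": float(r[i]),
                "wilcoxon_p": float(p),
                "direction": _direction(
                    float(r[i]), float(p), mm2 - mm1, r_threshold, p_threshold
                ),
                f"mean_meth_{g_best}": mm1,
                f"mean_meth_{g_worst}": mm2,
                f"mean_expr_{g_best}": me1,
                f"mean_expr_{g_worst}": me2,
            }
        )
    return pd.DataFrame(rows)


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file into ``{set_name: (description, genes)}``."""
    sets = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = (desc, genes)
    return sets


def hypergeom_enrichment(
    query,
    collections: dict[str, tuple[str, list[str]]],
    universe,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH adjustment.

    ``P(X >= overlap)`` per set after intersecting the set (and the
    query) with the universe; results sorted by raw p.
    """
    universe = set(universe)
    if not universe:
        raise ContractError("empty universe")
    query = set(query)
    extra = query - universe
    if extra:
        warnings.warn(f"{len(extra)} query gene(s) outside the universe; dropped")
        query &= universe
    M, N = len(universe), len(query)
    rows = []
    for name, (_desc, genes) in collections.items():
        members = set(genes) & universe
        k = len(members & query)
        n = len(members)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {"set_name": name, "set_size": n, "overlap": k,
             "universe_size": M, "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["p_value"] < alpha
        out = out.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    return out
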