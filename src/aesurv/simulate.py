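"""Synthetic multi-omics survival cohorts with planted structure.

The generator emulates the statistical structure the subtyping pipeline
assumes: two latent subtypes (G1/G2) separated by a block of informative
features in each omic, proportional-hazards survival with a higher hazard
for G2, independent exponential censoring, and a block of planted
"methylation-driven" genes whose methylation is anti-correlated with
expression and differs between subtypes.

Beyond the subtype label, each sample carries a continuous latent severity
that loads on the informative features and multiplies the hazard.  Real
tumor cohorts show graded risk within a molecular subtype; without this
component a classifier's risk score could never rank patients within a
subtype and concordance would be capped near the two-group ceiling.

Methylation is generated on the logit scale and squashed through a sigmoid
so beta-like values stay in (0, 1); driver coupling is induced by a shared
per-gene latent factor with opposite signs in methylation and expression,
with the coupling strength solved so the Spearman correlation matches the
requested target at large n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import io as _io
from .exceptions import ConfigurationError


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults are the package's reference conditions.

    ``effect_size`` is the mean shift of informative features between
    subtypes in within-group SD units.  ``hazard_ratio`` is the conditional
    G2-vs-G1 hazard ratio.  ``severity_hazard`` multiplies a per-sample
    standard-normal latent severity on the log-hazard scale and
    ``severity_loading`` is its loading on each informative feature.
    ``driver_corr`` is the target Spearman correlation between methylation
    and expression of planted driver genes.
    """

    n_samples: int = 400
    n_genes_expr: int = 1000
    n_cpg_meth: int = 1000
    n_informative: int = 100
    subtype_proportion: float = 0.385  # fraction of samples in G2
    effect_size: float = 2.0
    hazard_ratio: float = 3.0
    baseline_scale: float = 1000.0  # days
    censor_rate: float = 0.55
    n_drivers: int = 50
    driver_corr: float = -0.8
    severity_hazard: float = 1.0
    severity_loading: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        pos_int = {
            "n_samples": self.n_samples,
            "n_genes_expr": self.n_genes_expr,
            "n_cpg_meth": self.n_cpg_meth,
        }
        for name, v in pos_int.items():
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ConfigurationError(f"{name} must be a positive integer (got {v!r})")
        if self.n_informative < 0:
            raise ConfigurationError("n_informative must be non-negative")
        if self.n_informative > min(self.n_genes_expr, self.n_cpg_meth):
            raise ConfigurationError("n_informative exceeds matrix width")
        if not 0 < self.subtype_proportion < 1:
            raise ConfigurationError("subtype_proportion must lie in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ConfigurationError("hazard_ratio must be positive")
        if self.baseline_scale <= 0:
            raise ConfigurationError("baseline_scale must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ConfigurationError("censor_rate must lie in [0, 1)")
        if self.n_drivers < 0 or self.n_drivers > min(self.n_genes_expr, self.n_cpg_meth):
            raise ConfigurationError("n_drivers must lie in [0, min(n_genes_expr, n_cpg_meth)]")
        if self.n_informative + self.n_drivers > min(self.n_genes_expr, self.n_cpg_meth):
            raise ConfigurationError(
                "n_informative + n_drivers exceeds matrix width; shrink one of them"
            )
        if not -1 <= self.driver_corr <= 0:
            raise ConfigurationError("driver_corr must lie in [-1, 0]")


@dataclass
class SyntheticCohort:
    expr: pd.DataFrame  # genes x samples
    meth: pd.DataFrame  # cpg (gene-named) x samples
    clinical: pd.DataFrame  # indexed by sample id
    true_labels: pd.Series  # sample id -> "G1"/"G2"
    true_driver_genes: list[str]
    config: SyntheticConfig = field(repr=False, default=None)


def _driver_coupling(target_spearman: float, shift: float, pq: float) -> float:
    """Latent-factor loading that yields the target Spearman correlation.

    For jointly normal pairs, Spearman rho_s relates to Pearson rho via
    rho = 2*sin(pi*rho_s/6); the subtype shift contributes additional
    (anti-)covariance which is accounted for before solving for the
    shared-factor loading.
    """
    rho = abs(2.0 * np.sin(np.pi * target_spearman / 6.0))
    v = shift * shift * pq  # shift covariance (negated in the data)

    # variance per margin: a^2 + shift^2*pq + 1 ; covariance magnitude: a^2 + v
    def g(a2):
        return (a2 + v) / (a2 + shift**2 * pq + 1.0) - rho

    if g(0.0) >= 0:
        return 0.0  # shift alone already meets/overshoots the target
    return float(np.sqrt(brentq(g, 0.0, 1e4)))


def _solve_censor_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving expected censor fraction ``target``."""
    if target == 0:
        return 0.0

    def frac(mu):
        return float(np.mean(mu / (hazards + mu))) - target

    return brentq(frac, 1e-15, 1e6 * hazards.max())


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a cohort; bit-reproducible for a fixed ``config.seed``."""
    config.validate()
    c = config
    rng = np.random.default_rng(c.seed)
    n = c.n_samples

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = [f"gene_{i + 1:05d}" for i in range(max(c.n_genes_expr, c.n_cpg_meth))]
    expr_ids = gene_ids[: c.n_genes_expr]
    meth_ids = gene_ids[: c.n_cpg_meth]

    n2 = int(round(n * c.subtype_proportion))
    g = np.zeros(n)
    g[rng.permutation(n)[:n2]] = 1.0  # 1 = G2 (poor prognosis)
    u = rng.standard_normal(n)  # latent severity

    expr = rng.standard_normal((c.n_genes_expr, n))
    meth_logit = rng.standard_normal((c.n_cpg_meth, n))

    inf = slice(0, c.n_informative)
    shift = c.effect_size * g + c.severity_loading * u
    expr[inf] += shift
    # same-direction shift in methylation: informative genes are
    # hypermethylated AND overexpressed in G2, so they do not satisfy the
    # negative-correlation driver rule by accident
    meth_logit[inf] += shift

    driver_genes: list[str] = []
    if c.n_drivers:
        pq = c.subtype_proportion * (1 - c.subtype_proportion)
        a = _driver_coupling(c.driver_corr, c.effect_size, pq)
        lo = c.n_informative
        hi = lo + c.n_drivers
        z = rng.standard_normal((c.n_drivers, n))
        expr[lo:hi] += c.effect_size * g - a * z
        meth_logit[lo:hi] += -c.effect_size * g + a * z
        driver_genes = gene_ids[lo:hi]

    meth = expit(meth_logit)

    log_hazard = np.log(c.hazard_ratio) * g + c.severity_hazard * u
    hazards = np.exp(log_hazard) / c.baseline_scale
    event_time = rng.exponential(1.0, n) / hazards
    if c.censor_rate > 0:
        mu = _solve_censor_rate(hazards, c.censor_rate)
        censor_time = rng.exponential(1.0 / mu, n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-6)  # strictly positive

    grade_probs = np.where(
        g[:, None] == 1, [[0.10, 0.30, 0.60]], [[0.50, 0.35, 0.15]]
    )
    grades = np.array(["II", "III", "IV"])
    grade = grades[
        (rng.random(n)[:, None] > grade_probs.cumsum(axis=1)).sum(axis=1)
    ]
    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": 50.0 + 5.0 * g + rng.normal(0.0, 10.0, n),
            "gender": rng.choice(["female", "male"], n),
            "grade": grade,
            "tumor_type": np.where(rng.random(n) < 0.1 + 0.5 * g, "GBM", "LGG"),
            "idh_status": np.where(
                rng.random(n) < 0.7 - 0.4 * g, "mutant", "wildtype"
            ),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    labels = pd.Series(
        np.where(g == 1, "G2", "G1"), index=clinical.index, name="true_label"
    )
    return SyntheticCohort(
        expr=pd.DataFrame(expr, index=expr_ids, columns=sample_ids),
        meth=pd.DataFrame(meth, index=meth_ids, columns=sample_ids),
        clinical=clinical,
        true_labels=labels,
        true_driver_genes=driver_genes,
        config=c,
    )


def generate_adversarial_cohort(
    n_samples: int = 300,
    n_informative: int = 60,
    n_distractor: int = 150,
    n_noise: int = 90,
    distractor_df: float = 1.5,
    distractor_scale: float = 5.0,
    effect_size: float = 2.0,
    hazard_ratio: float = 3.0,
    severity_hazard: float = 1.0,
    severity_loading: float = 0.5,
    subtype_proportion: float = 0.4,
    censor_rate: float = 0.55,
    baseline_scale: float = 1000.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Single-omic cohort whose dominant-variance axes are survival-orthogonal.

    A block of heavy-tailed Student-t distractor features carries far more
    variance than the subtype-informative block, so a variance-ranked
    linear projection (PCA) spends its components on distractors while the
    survival signal lives elsewhere.  Used to contrast the autoencoder
    path (whose bounded unit-interval input conditioning compresses the
    heavy tails) against the PCA baseline.
    """
    rng = np.random.default_rng(seed)
    n = n_samples
    n2 = int(round(n * subtype_proportion))
    g = np.zeros(n)
    g[rng.permutation(n)[:n2]] = 1.0
    u = rng.standard_normal(n)
    inf = rng.standard_normal((n_informative, n)) + effect_size * g + severity_loading * u
    dis = rng.standard_t(distractor_df, size=(n_distractor, n)) * distractor_scale
    noise = rng.standard_normal((n_noise, n))
    X = np.vstack([inf, dis, noise])
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    expr = pd.DataFrame(
        X, index=[f"gene_{i + 1:05d}" for i in range(X.shape[0])], columns=sample_ids
    )
    log_hazard = np.log(hazard_ratio) * g + severity_hazard * u
    hazards = np.exp(log_hazard) / baseline_scale
    event_time = rng.exponential(1.0, n) / hazards
    mu = _solve_censor_rate(hazards, censor_rate)
    censor_time = rng.exponential(1.0 / mu, n) if censor_rate else np.full(n, np.inf)
    clinical = pd.DataFrame(
        {
            "time": np.maximum(np.minimum(event_time, censor_time), 1e-6),
            "event": (event_time <= censor_time).astype(int),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    labels = pd.Series(
        np.where(g == 1, "G2", "G1"), index=clinical.index, name="true_label"
    )
    return SyntheticCohort(
        expr=expr, meth=expr.iloc[:0], clinical=clinical,
        true_labels=labels, true_driver_genes=[],
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write expr.tsv / meth.tsv / clinical.tsv / truth.tsv into ``directory``.

    Output bytes are a pure function of the cohort, so two writes of the
    same cohort are identical.
    """
    if not str(directory):
        raise ValueError("empty output directory path")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": directory / "expr.tsv",
        "meth": directory / "meth.tsv",
        "clinical": directory / "clinical.tsv",
        "truth": directory / "truth.tsv",
    }
    _io.write_omics(cohort.expr, paths["expr"])
    _io.write_omics(cohort.meth, paths["meth"])
    _io.write_clinical(cohort.clinical, paths["clinical"])
    truth = pd.concat(
        [
            pd.DataFrame(
                {"record": "subtype", "id": cohort.true_labels.index,
                 "value": cohort.true_labels.values}
            ),
            pd.DataFrame(
                {"record": "driver", "id": cohort.true_driver_genes, "value": "1"}
            ),
        ],
        ignore_index=True,
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_truth(path) -> tuple[pd.Series, list[str]]:
    """Read a truth.tsv back into (labels, driver gene list)."""
    t = pd.read_csv(path, sep="\t")
    lab = t[t["record"] == "subtype"].set_index("id")["value"]
    lab.index.name = "sample_id"
    drivers = t.loc[t["record"] == "driver", "id"].astype(str).tolist()
    return lab, drivers
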