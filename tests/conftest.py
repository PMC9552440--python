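"""Shared fixtures: small synthetic cohorts and one full pipeline run.

Expensive artifacts (the reference cohort, the trained autoencoder and
everything downstream of it) are session-scoped so the whole suite pays
for them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from aesurv import preprocess as prep
from aesurv.autoencoder import Autoencoder, encode
from aesurv.classify import crossvalidate
from aesurv.simulate import SyntheticConfig, generate_cohort
from aesurv.subtype import cox_screen, kmeans_select, name_subtypes

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


SMALL = SyntheticConfig(
    n_samples=120,
    n_genes_expr=150,
    n_cpg_meth=150,
    n_informative=40,
    n_drivers=20,
    seed=5,
)

REFERENCE = SyntheticConfig(n_samples=400, effect_size=2.0, hazard_ratio=3.0, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL)


@pytest.fixture(scope="session")
def reference_cohort():
    """The standard study conditions: n=400, effect size 2, hazard ratio 3."""
    return generate_cohort(REFERENCE)


def preprocess_cohort(cohort, epsilon: float = 0.01):
    """MAD filter + robust scale + unit squash per omic; returns dicts."""
    scaled, squashed = {}, {}
    for name, m in (("expr", cohort.expr), ("meth", cohort.meth)):
        m = prep.mad_filter(m)
        s = prep.apply_scaler(m, prep.fit_scaler(m))
        scaled[name] = s
        squashed[name] = prep.squash_to_unit(s, epsilon)
    return scaled, squashed


@pytest.fixture(scope="session")
def reference_pipeline(reference_cohort):
    """Full pipeline artifacts on the reference cohort (shared by tests)."""
    scaled, squashed = preprocess_cohort(reference_cohort)
    stacked = pd.concat([squashed["expr"], squashed["meth"]], axis=0, keys=["expr", "meth"])
    stacked.index = [f"{o}:{f}" for o, f in stacked.index]
    model = Autoencoder(
        hidden_sizes=(500, 100, 500), learning_rate=1e-3, epochs=20, random_state=1
    ).fit(stacked.T.to_numpy())
    latent = encode(model, stacked)
    screen = cox_screen(latent, reference_cohort.clinical, alpha=0.05)
    kept = latent.loc[:, screen["selected"].to_numpy()]
    selection = kmeans_select(kept, k_min=2, k_max=6, seed=1)
    result = name_subtypes(selection, reference_cohort.clinical)
    report = crossvalidate(
        scaled, reference_cohort.clinical, result.labels, n_splits=10, seed=1
    )
    return {
        "cohort": reference_cohort,
        "scaled": scaled,
        "squashed": squashed,
        "stacked": stacked,
        "model": model,
        "latent": latent,
        "screen": screen,
        "selection": selection,
        "result": result,
        "cv_report": report,
    }


@pytest.fixture(scope="session")
def null_screen():
    """Univariate Cox screen of 1000 pure-noise features (n=400)."""
    from aesurv.subtype import univariate_cox

    rng = np.random.default_rng(2024)
    n, F = 400, 1000
    X = rng.standard_normal((n, F))
    t = rng.exponential(1000.0, n)
    c = rng.exponential(1500.0, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(float)
    return univariate_cox(X, time, event, alpha=0.05)


NULL_COHORT = SyntheticConfig(
    n_samples=200, n_genes_expr=150, n_cpg_meth=150, n_informative=40,
    n_drivers=0, effect_size=0.0, hazard_ratio=1.0, severity_hazard=0.0,
    severity_loading=0.0, seed=21,
)


@pytest.fixture(scope="session")
def null_cohort():
    """All signal knobs at zero: labels and features carry no survival signal."""
    return generate_cohort(NULL_COHORT)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
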