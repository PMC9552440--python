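"""PCA alternative to the autoencoder for head-to-head comparison.

One hundred principal components (matching the bottleneck width) replace
the learned latent features; every downstream stage — Cox screening,
K-means cluster selection, prognosis-ordered naming, cross-validation —
is the same shared code as the main path.  Component signs are fixed
(largest-magnitude loading positive) so the transform is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import classify as _classify
from . import subtype as _subtype
from .exceptions import ContractError


@dataclass
class PcaState:
    components: np.ndarray  # (n_components, n_features) orthonormal rows
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    feature_ids: list[str]


def pca_transform(data: pd.DataFrame, n_components: int = 100) -> tuple[PcaState, pd.DataFrame]:
    """Project samples onto the top principal components.

    ``data`` is samples-by-features.  Returns the fitted state and a
    samples-by-components frame with columns ``PC_001`` ...
    """
    X = data.to_numpy(dtype=float)
    if n_components > min(X.shape):
        raise ContractError(
            f"n_components={n_components} exceeds min(n_samples, n_features)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    # deterministic sign: the largest-|.| loading of each component is positive
    flip = np.sign(comps[np.arange(len(comps)), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    comps *= flip[:, None]
    scores *= flip[None, :]
    width = max(3, len(str(n_components)))
    names = [f"PC_{i + 1:0{width}d}" for i in range(n_components)]
    state = PcaState(
        components=comps,
        mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        feature_ids=list(data.columns.astype(str)),
    )
    return state, pd.DataFrame(scores, index=data.index, columns=names)


def pca_pipeline(
    omics: dict[str, pd.DataFrame],
    clinical: pd.DataFrame,
    n_components: int = 100,
    alpha: float = 0.05,
    k_min: int = 2,
    k_max: int = 6,
    seed: int = 0,
    crossvalidate: bool = False,
    cv_kwargs: dict | None = None,
):
    """PCA counterpart of the autoencoder path.

    Concatenates the omics feature-wise, projects onto ``n_components``
    principal components and runs the shared downstream machinery
    (``cox_screen`` → ``kmeans_select`` → ``name_subtypes`` and optionally
    ``crossvalidate``).  A singleton cluster still yields a SubtypeResult;
    the classifier stage is what refuses it.

    Returns ``(SubtypeResult, screen DataFrame, CVReport | None)``.
    """
    stacked = pd.concat(list(omics.values()), axis=0)
    state, latent = pca_transform(stacked.T, n_components=n_components)
    screen = _subtype.cox_screen(latent, clinical, alpha=alpha)
    kept = latent.loc[:, screen["selected"].to_numpy()]
    if kept.shape[1] == 0:
        raise ContractError(
            "no survival-associated principal component at this alpha; relax alpha"
        )
    selection = _subtype.kmeans_select(kept, k_min=k_min, k_max=k_max, seed=seed)
    result = _subtype.name_subtypes(selection, clinical)
    report = None
    if crossvalidate:
        report = _classify.crossvalidate(
            omics, clinical, result.labels, seed=seed, tag="pca", **(cv_kwargs or {})
        )
    return result, screen, report
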