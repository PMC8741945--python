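"""Genotype principal component analysis.

Columns (sites) are mean-imputed at missing calls, centred, optionally
scaled to unit variance, then decomposed by full SVD (equivalent to an
eigendecomposition of the sample covariance, as R's ``prcomp`` computes).
Constant sites after imputation carry no information and are dropped with
a warning. Component signs are arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import MISSING, GenotypeMatrix


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components, columns PC1..PCk
    loadings: np.ndarray  # sites x components (for the retained sites)
    variance_explained: np.ndarray  # fraction per component, non-increasing
    retained_sites: np.ndarray  # indices of non-constant sites used


def pca_genotypes(
    genotypes: GenotypeMatrix,
    n_components: int | None = None,
    scale: bool = False,
) -> PcaResult:
    """PCA of the dosage matrix (samples as observations, sites as
    variables). ``scale=False`` centres only, matching the usual prcomp
    default for genotype data."""
    if genotypes.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    x = genotypes.dosages.astype(float)
    miss = x == MISSING
    x[miss] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    x = np.where(np.isnan(x), col_mean[None, :], x)

    sd = x.std(axis=0, ddof=1)
    keep = sd > 0.0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant sites before PCA")
    if keep.sum() < 2:
        raise ValueError("fewer than two polymorphic sites after imputation")
    x = x[:, keep]
    if scale:
        x = x / x.std(axis=0, ddof=1)[None, :]

    max_rank = min(genotypes.n_samples - 1, x.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=max_rank, svd_solver="full")
    scores = pca.fit_transform(x)
    result = PcaResult(
        scores=pd.DataFrame(
            scores[:, :k],
            index=genotypes.samples,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        loadings=pca.components_[:k].T,
        variance_explained=pca.explained_variance_ratio_[:k],
        retained_sites=np.flatnonzero(keep),
    )
    return result
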