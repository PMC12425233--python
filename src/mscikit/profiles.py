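"""Expression-profile clustering and reproducibility QC.

K-means on per-gene stage Z-score profiles recovers the classical
spermatogenesis expression programs (k = 12 by precedent with earlier
microarray work); log2 Pearson correlations and sample-level PCA serve as
replicate/stage QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

DEFAULT_K = 12
DEFAULT_RESTARTS = 50


class ProfileError(ValueError):
    pass


def zscore_stage_profile(stage_means: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Row-wise Z-scores of per-gene stage means.

    Uses the population standard deviation (n denominator) — with only three
    stages per profile this is a convention, documented as such.  Genes with
    zero variance across stages carry no profile shape and are excluded;
    their ids are returned alongside.
    """
    if stage_means.shape[1] < 2:
        raise ProfileError("need at least two stages to form a profile")
    mat = stage_means.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    z = np.full_like(mat, np.nan)
    z[~flat] = (mat[~flat] - mean[~flat]) / sd[~flat]
    profiles = pd.DataFrame(z, index=stage_means.index, columns=stage_means.columns)
    excluded = stage_means.index[flat]
    return profiles.loc[~flat], excluded


@dataclass
class ProfileClustering:
    k: int
    labels: pd.Series  # gene -> cluster in 1..k
    centroids: pd.DataFrame  # cluster x stage, Z units
    proportions: pd.Series  # cluster -> gene share
    inertia: float
    seed: int


def kmeans_profiles(
    profiles: pd.DataFrame,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
) -> ProfileClustering:
    """Best-of-restarts k-means++ on Z-score profiles (deterministic per seed)."""
    if k < 2:
        raise ProfileError("k must be at least 2")
    if len(profiles) < k:
        raise ProfileError(f"cannot form {k} clusters from {len(profiles)} profiles")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, init="k-means++")
    labels = km.fit_predict(profiles.to_numpy(dtype=float)) + 1
    labels = pd.Series(labels, index=profiles.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_, index=range(1, k + 1), columns=profiles.columns
    )
    proportions = labels.value_counts(normalize=True).reindex(range(1, k + 1), fill_value=0.0)
    return ProfileClustering(
        k=k,
        labels=labels,
        centroids=centroids,
        proportions=proportions,
        inertia=float(km.inertia_),
        seed=seed,
    )


def pearson_log2(x, y, pseudocount: float = 1.0) -> float:
    """Pearson correlation of two samples on the log2(value + pc) scale."""
    x = np.log2(np.asarray(x, dtype=float) + pseudocount)
    y = np.log2(np.asarray(y, dtype=float) + pseudocount)
    if x.size != y.size or x.size < 3:
        raise ProfileError("need two equal-length vectors of >= 3 genes")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_matrix(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """All-pairs sample correlation matrix on log2 expression."""
    cols = list(expr.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = pearson_log2(expr[a], expr[b], pseudocount)
            out.loc[a, b] = out.loc[b, a] = r
    return out


def pca_samples(
    expr: pd.DataFrame, pseudocount: float = 1.0, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA of log2 expression (genes are features).

    Returns per-sample coordinates and the variance-explained fractions
    (non-increasing, summing to <= 1).
    """
    if expr.shape[1] < 3:
        raise ProfileError("PCA needs at least three samples")
    mat = np.log2(expr.to_numpy(dtype=float).T + pseudocount)
    mat = mat - mat.mean(axis=0, keepdims=True)
    if not np.any(mat):
        raise ProfileError("constant expression matrix; PCA undefined")
    if scale:
        sd = mat.std(axis=0, ddof=0, keepdims=True)
        mat = mat / np.where(sd == 0, 1.0, sd)
    n_comp = min(mat.shape[0] - 1, mat.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(mat)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=expr.columns, columns=cols),
        pca.explained_variance_ratio_,
    )
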