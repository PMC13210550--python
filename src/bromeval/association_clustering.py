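"""Multivariate trait association and clustering.

z-score standardization, K-means with k-means++ initialization and
best-of-restarts selection, cluster-number selection by elbow curve plus
mean silhouette, PCA projection with a deterministic sign convention, and
the Mantel permutation test between distance matrices.

Clustering here typically operates on very few objects (genotype-level mean
vectors of a handful of accessions); the functions permit that but warn when
the silhouette is computed on fewer than ``2k`` points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = [
    "zscore",
    "kmeans_fit",
    "select_k",
    "pca_project",
    "mantel",
    "euclidean_distance_matrix",
    "genotype_profiles",
    "ClusterResult",
    "MantelResult",
]


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize columns to zero mean and unit variance (n-1 SD).

    Constant columns carry no ordering information and break the scaling;
    they are dropped with a warning.  Column means/SDs are attached as
    ``DataFrame.attrs['center'] / ['scale']`` for inverse transforms.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two rows to standardize")
    means = matrix.mean()
    sds = matrix.std(ddof=1)
    constant = sds[sds == 0].index
    if len(constant):
        warnings.warn(
            f"dropping constant columns: {list(constant)}", UserWarning, stacklevel=2
        )
    keep = [c for c in matrix.columns if c not in set(constant)]
    out = (matrix[keep] - means[keep]) / sds[keep]
    out.attrs["center"] = means[keep]
    out.attrs["scale"] = sds[keep]
    return out


def genotype_profiles(
    table: pd.DataFrame,
    indicators: list[str] | None = None,
    by: str = "genotype",
) -> pd.DataFrame:
    """Genotype-level indicator means over all years and blocks.

    This is the standard reduction of a multi-year trial to one multi-trait
    vector per genotype for clustering / ranking.
    """
    if indicators is None:
        indicators = [
            c for c in table.columns if c not in ("genotype", "year", "block")
        ]
    return table.groupby(by, observed=True)[indicators].mean()


@dataclass(frozen=True)
class ClusterResult:
    k: int
    assignments: pd.Series  # labels in 1..k
    centroids: np.ndarray
    wss: float
    silhouette: float
    restart_wss: tuple[float, ...]
    n_restarts: int


def kmeans_fit(
    X: pd.DataFrame,
    k: int,
    n_restarts: int = 25,
    max_iter: int = 300,
    seed: int | None = None,
) -> ClusterResult:
    """K-means with k-means++ starts, keeping the best of ``n_restarts`` runs.

    Restarts are run individually so the per-restart within-cluster SS trace
    is available and the returned solution provably has the minimum WSS among
    them.  Deterministic given ``seed``.  Silhouette is NaN for k = 1 and
    k = n (undefined); a warning is issued when n < 2k (silhouette on so few
    points is fragile).
    """
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    values = X.to_numpy(dtype=float)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_restarts)]
    best = None
    trace = []
    for rs in run_seeds:
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter, random_state=rs
        ).fit(values)
        trace.append(float(km.inertia_))
        if best is None or km.inertia_ < best.inertia_:
            best = km
    if 2 <= k <= n - 1:
        if n < 2 * k:
            warnings.warn(
                f"silhouette computed on only {n} points for k={k}",
                UserWarning,
                stacklevel=2,
            )
        sil = float(silhouette_score(values, best.labels_))
    else:
        sil = float("nan")
    assignments = pd.Series(best.labels_ + 1, index=X.index, name="cluster")
    return ClusterResult(
        k=k,
        assignments=assignments,
        centroids=best.cluster_centers_,
        wss=float(best.inertia_),
        silhouette=sil,
        restart_wss=tuple(trace),
        n_restarts=n_restarts,
    )


def select_k(
    X: pd.DataFrame,
    k_range: range | list[int],
    seed: int | None = None,
    n_restarts: int = 25,
) -> tuple[int, pd.Series, pd.Series]:
    """Choose k by maximum mean silhouette; report the elbow (WSS) curve too.

    Ties in silhouette go to the smaller k.  Returns
    ``(k_best, wss_curve, silhouette_curve)`` indexed by k.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    if ks[0] < 2 or ks[-1] > len(X) - 1:
        raise ValueError("k range must lie within [2, n_rows - 1]")
    wss, sil = {}, {}
    for k in ks:
        res = kmeans_fit(X, k, n_restarts=n_restarts, seed=seed)
        wss[k] = res.wss
        sil[k] = res.silhouette
    sil_curve = pd.Series(sil).sort_index()
    k_best = int(sil_curve.idxmax())  # idxmax returns the first (smallest) max
    return k_best, pd.Series(wss).sort_index(), sil_curve


def pca_project(
    X: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project onto principal components with a fixed sign convention.

    Components are sign-fixed so each one's largest-magnitude loading is
    positive (PCA signs are otherwise arbitrary).  Returns the score matrix
    and the explained-variance fractions (non-increasing, summing <= 1).
    """
    values = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(values - values.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(values)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] = -load
            scores[:, j] = -scores[:, j]
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return pd.DataFrame(scores, index=X.index, columns=cols), pca.explained_variance_ratio_


def euclidean_distance_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Square Euclidean distance matrix with row/column labels."""
    d = squareform(pdist(X.to_numpy(dtype=float)))
    return pd.DataFrame(d, index=X.index, columns=X.index)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    alternative: str


def _check_distance_matrix(d: np.ndarray, name: str) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError(f"{name} must have a zero diagonal")


def mantel(
    d1,
    d2,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test of association between two distance matrices.

    r is the Pearson correlation of the strictly-lower-triangle entries; the
    null is generated by permuting the objects of the second matrix (rows and
    columns simultaneously).  p uses the add-one correction
    ``(#{r_perm >= r} + 1) / (n_perm + 1)`` (one-tailed "greater" by default;
    ``alternative="two-sided"`` compares |r|), so p is never exactly 0.
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    _check_distance_matrix(a, "d1")
    _check_distance_matrix(b, "d2")
    if a.shape != b.shape or a.shape[0] < 4:
        raise ValueError("matrices must have equal dimension >= 4")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    n = a.shape[0]
    il = np.tril_indices(n, k=-1)
    x = a[il]
    x = (x - x.mean()) / x.std()
    y0 = b[il]

    def corr(y: np.ndarray) -> float:
        ys = (y - y.mean()) / y.std()
        return float(np.mean(x * ys))

    r_obs = corr(y0)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(b[np.ix_(perm, perm)][il])
        if alternative == "greater":
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed, alternative=alternative)
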