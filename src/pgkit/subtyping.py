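"""Consensus-clustering subtype discovery with CDF/delta-area/silhouette
diagnostics, plus cluster merging and PCA projection.

Each repetition subsamples a fraction of the samples (pFeature = 1, so the
sample-sample Spearman distance matrix is fixed and computed once),
hierarchically clusters them (complete linkage on 1 - Spearman correlation)
and cuts at k; the consensus matrix entry M_k(i, j) is the fraction of
co-sampled repetitions in which i and j co-clustered.  The final
assignment re-clusters 1 - M_k; k is chosen by mean silhouette among k
values whose delta-area clears an elbow threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io import OmicsMatrix

log = logging.getLogger(__name__)


def select_features(matrix: OmicsMatrix, top_fraction: float = 0.5
                    ) -> list[str]:
    """Top-variance features: the floor(top_fraction * m) largest-SD rows.

    SD is computed on non-missing values; ties at the boundary go to the
    lexicographically smaller feature ID.
    """
    sd = matrix.values.std(axis=1, ddof=1, skipna=True).fillna(0.0)
    if (sd == 0).all():
        raise ValueError("all features constant")
    k = max(1, int(top_fraction * len(sd)))
    order = sorted(sd.index, key=lambda f: (-sd[f], f))
    return order[:k]


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, pd.DataFrame]       # k -> samples x samples in [0,1]
    assignments: dict[int, pd.Series]        # k -> sample -> cluster label
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # k -> (grid, CDF)
    area: dict[int, float]                   # A(k)
    delta_area: dict[int, float]             # Delta(k)
    silhouette: dict[int, float]
    chosen_k: int | None = None
    confident: bool = True
    features_used: list[str] = field(default_factory=list)


def _spearman_distance(values: pd.DataFrame) -> np.ndarray:
    """1 - Spearman correlation between sample columns (pairwise-complete)."""
    corr = values.corr(method="spearman", min_periods=3)
    d = 1.0 - corr.to_numpy()
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def consensus_cluster(matrix: OmicsMatrix, k_range, n_reps: int = 500,
                      p_item: float = 0.8, rng_seed: int = 0,
                      linkage_method: str = "complete",
                      min_coverage: float = 0.5) -> ConsensusResult:
    """Subsampled hierarchical consensus clustering over ``k_range``."""
    ks = sorted(set(int(k) for k in k_range))
    n = matrix.values.shape[1]
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie in [2, {n - 1}]")
    if n_reps < 50:
        raise ValueError("n_reps must be >= 50")

    vals = matrix.values
    coverage = vals.notna().mean(axis=0)
    keep = coverage[coverage >= min_coverage].index
    if len(keep) < n:
        log.warning("consensus_cluster: excluded %d samples with <%.0f%% "
                    "coverage", n - len(keep), 100 * min_coverage)
        vals = vals[keep]
        n = len(keep)
    samples = list(vals.columns)

    dist = _spearman_distance(vals)
    if np.isnan(dist).any():
        raise ValueError("undefined sample-sample correlation (too few "
                         "pairwise-complete features)")

    rng = np.random.default_rng(rng_seed)
    sub_n = int(math.floor(p_item * n))
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sample = np.zeros((n, n))
    for _ in range(n_reps):
        idx = np.sort(rng.choice(n, size=sub_n, replace=False))
        co_sample[np.ix_(idx, idx)] += 1
        sub = dist[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method=linkage_method)
        for k in ks:
            labels = fcluster(Z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same
    if np.any((co_sample == 0) & ~np.eye(n, dtype=bool)):
        raise ValueError("some sample pairs never co-sampled; increase n_reps")

    result = ConsensusResult(k_range=ks, consensus={}, assignments={},
                             cdf={}, area={}, delta_area={}, silhouette={},
                             features_used=list(vals.index))
    grid = np.linspace(0.0, 1.0, 101)
    prev_area = None
    iu = np.triu_indices(n, k=1)
    for k in ks:
        with np.errstate(invalid="ignore"):
            M = np.where(co_sample > 0, co_cluster[k] / co_sample, 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        Mdf = pd.DataFrame(M, index=samples, columns=samples)
        result.consensus[k] = Mdf

        Zf = linkage(squareform(np.clip(1.0 - M, 0, None), checks=False),
                     method=linkage_method)
        labels = fcluster(Zf, t=k, criterion="maxclust")
        result.assignments[k] = pd.Series(labels, index=samples)

        vals_ut = M[iu]
        cdf = np.searchsorted(np.sort(vals_ut), grid, side="right") / vals_ut.size
        area = float(np.trapezoid(cdf, grid))
        result.cdf[k] = (grid, cdf)
        result.area[k] = area
        if prev_area is None:
            result.delta_area[k] = area
        else:
            result.delta_area[k] = ((area - prev_area) / prev_area
                                    if prev_area > 0 else 0.0)
        prev_area = area

        dmat = np.clip(1.0 - M, 0.0, None)
        np.fill_diagonal(dmat, 0.0)
        if len(np.unique(labels)) > 1:
            result.silhouette[k] = float(silhouette_score(
                dmat, labels, metric="precomputed"))
        else:
            result.silhouette[k] = float("nan")
    return result


def choose_k(result: ConsensusResult, elbow_threshold: float = 0.025,
             silhouette_floor: float = 0.25) -> int:
    """Mean silhouette among elbow-supported k; ties go to the smaller k.

    Always returns a k; ``result.confident`` is cleared when no k has
    silhouette above ``silhouette_floor`` (no cluster support).
    """
    candidates = [k for k in result.k_range
                  if result.delta_area.get(k, 0.0) >= elbow_threshold]
    if not candidates:
        candidates = list(result.k_range)
    def sil(k: int) -> float:
        v = result.silhouette.get(k, float("nan"))
        return -1.0 if not np.isfinite(v) else v

    best = min(candidates, key=lambda k: (-round(sil(k), 12), k))
    result.chosen_k = best
    result.confident = max(sil(k) for k in result.k_range) >= silhouette_floor
    return best


def merge_clusters(assignments: pd.Series, merge_map: dict) -> pd.Series:
    """Relabel cluster assignments through ``merge_map`` (must be total)."""
    unmapped = sorted(set(assignments.unique()) - set(merge_map))
    if unmapped:
        raise ValueError(f"merge map missing labels: {unmapped}")
    return assignments.map(merge_map)


def project_pca(matrix: OmicsMatrix, n_components: int = 2) -> pd.DataFrame:
    """Centred-SVD sample coordinates; missing values mean-imputed per row.

    Component sign is fixed so the largest-magnitude loading is positive.
    """
    vals = matrix.values.to_numpy(dtype=float)
    row_mean = np.nanmean(vals, axis=1, keepdims=True)
    filled = np.where(np.isnan(vals), row_mean, vals)
    X = filled.T  # samples x features
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for i in range(n_components):
        load = pca.components_[i]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, i] *= -1
    out = pd.DataFrame(coords, index=matrix.values.columns,
                       columns=[f"PC{i + 1}" for i in range(n_components)])
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return out
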