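"""Single-sample enrichment scores: GSVA-style KS walk, MGPS, TF activity.

One enrichment engine serves pathway scores, TF-target activity and
set-based kinase activity: per gene a cross-sample expression statistic
(Gaussian-kernel cumulative density by default, empirical CDF optionally),
per sample a ranking of genes by that statistic, and a weighted
Kolmogorov-Smirnov random walk over the ranking whose in-set increments are
proportional to ``|rank statistic|^tau``.  The score is the maximum
positive deviation of the walk minus the magnitude of its maximum negative
deviation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import GeneSetCollection, OmicsMatrix
from .diffexp import zscore_rows

log = logging.getLogger(__name__)


def _expression_statistic(values: np.ndarray, kcdf: str) -> np.ndarray:
    """Cross-sample statistic per gene row; NaN-aware."""
    out = np.full(values.shape, np.nan)
    for i, row in enumerate(values):
        obs = ~np.isnan(row)
        x = row[obs]
        if x.size == 0:
            continue
        if kcdf == "gaussian":
            sd = x.std(ddof=1) if x.size > 1 else 0.0
            h = sd / 4.0 if sd > 0 else 1e-8
            z = norm.cdf((x[:, None] - x[None, :]) / h).mean(axis=1)
        elif kcdf == "ecdf":
            order = x.argsort(kind="mergesort").argsort(kind="mergesort")
            z = (order + 1.0) / x.size
        else:
            raise ValueError(f"unknown kcdf {kcdf!r}")
        out[i, obs] = z
    return out


def ks_walk_score(in_set: np.ndarray, weights: np.ndarray,
                  tau: float = 1.0) -> float:
    """Max-deviation KS walk score over an ordered gene list.

    ``in_set`` marks set members in ranking order (best rank first);
    ``weights`` are the corresponding |rank statistic| values.  In-set
    steps rise by ``w^tau`` (normalized), out-of-set steps fall by
    ``1/(m - |S|)``; the score is the maximum positive deviation minus the
    magnitude of the maximum negative deviation.
    """
    in_set = np.asarray(in_set, dtype=bool)
    m = in_set.size
    n_in = int(in_set.sum())
    if n_in == 0 or n_in == m:
        return 0.0
    w = np.abs(np.asarray(weights, dtype=float)) ** tau
    denom_in = w[in_set].sum()
    if denom_in == 0:
        return 0.0
    steps = np.where(in_set, w / denom_in, -1.0 / (m - n_in))
    walk = np.cumsum(steps)
    return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))


def gsva_score(matrix: OmicsMatrix, sets: GeneSetCollection, tau: float = 1.0,
               min_set_size: int = 5, kcdf: str = "gaussian") -> pd.DataFrame:
    """Per-sample enrichment score for each gene set (sets x samples).

    Sets with fewer than ``min_set_size`` members present in the matrix are
    dropped with a warning; genes missing in a given sample are excluded
    from that sample's ranking.
    """
    features = matrix.values.index
    n_samples = matrix.values.shape[1]
    if n_samples < 3:
        raise ValueError("gsva_score needs >= 3 samples")
    usable = {}
    for name in sets.names():
        members = sets[name] & set(features)
        if len(members) < min_set_size:
            log.warning("gsva_score: set %r dropped (%d members present < %d)",
                        name, len(members), min_set_size)
            continue
        usable[name] = members
    if not usable:
        return pd.DataFrame(columns=matrix.values.columns)

    stat = _expression_statistic(matrix.values.to_numpy(dtype=float), kcdf)
    feat_pos = {f: i for i, f in enumerate(features)}
    scores = pd.DataFrame(np.nan, index=list(usable),
                          columns=matrix.values.columns)
    for j, sample in enumerate(matrix.values.columns):
        col = stat[:, j]
        obs = ~np.isnan(col)
        idx = np.where(obs)[0]
        if idx.size < 3:
            continue
        order = idx[np.argsort(-col[idx], kind="mergesort")]
        mj = order.size
        # symmetric rank statistic: extremes weigh most, mid-ranks least
        ranks = np.arange(1, mj + 1)
        weight = np.abs(mj / 2.0 - ranks)
        member_mask = {name: np.fromiter(
            (features[i] in members for i in order), dtype=bool, count=mj)
            for name, members in usable.items()}
        for name in usable:
            scores.loc[name, sample] = ks_walk_score(member_mask[name],
                                                     weight, tau)
    return scores


def mgps(matrix: OmicsMatrix, cellcycle_set: set[str],
         min_set_size: int = 5) -> pd.Series:
    """Multi-gene proliferation score: mean row-z abundance of the set.

    The matrix rows are z-scored across samples first; the per-sample score
    is the missing-aware mean over set members present in the matrix.
    """
    members = sorted(set(cellcycle_set) & set(matrix.values.index))
    if len(members) < min_set_size:
        raise ValueError(
            f"cell-cycle set intersects only {len(members)} features "
            f"(< {min_set_size})")
    z = matrix if matrix.scale == "zscore" else zscore_rows(matrix)
    return z.values.loc[members].mean(axis=0, skipna=True).rename("mgps")


def tf_activity(matrix: OmicsMatrix, tf_target_sets: GeneSetCollection,
                tau: float = 1.0, min_set_size: int = 5,
                kcdf: str = "gaussian") -> pd.DataFrame:
    """Transcription-factor activity: the enrichment engine over regulons."""
    return gsva_score(matrix, tf_target_sets, tau=tau,
                      min_set_size=min_set_size, kcdf=kcdf)
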