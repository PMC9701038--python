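"""Mutational-signature extraction: 96-channel catalogs, NMF, cosine matching.

The catalog counts single-base substitutions in their trinucleotide context
(pyrimidine-centred, canonical 96-channel ordering).  Non-negative matrix
factorization with multiplicative updates (Frobenius objective, best of
``n_restarts`` random restarts) decomposes the catalog into signatures and
per-sample exposures; the number of signatures is chosen by an elbow rule on
reconstruction error combined with a restart-stability requirement; each
extracted signature is matched to a reference catalog by cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF

from .io import CHANNELS_96, MutationTable, channel_of

log = logging.getLogger(__name__)


@dataclass
class MutationCatalog:
    """96 x samples matrix of trinucleotide substitution counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(CHANNELS_96):
            raise ValueError("catalog rows must be the canonical 96 channels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class SignatureDecomposition:
    W: pd.DataFrame                 # 96 x K, columns sum to 1
    H: pd.DataFrame                 # K x samples, columns sum to 1
    K: int
    reconstruction_error: float
    errors_by_k: dict[int, float] = field(default_factory=dict)
    matches: pd.DataFrame | None = None   # signature, reference, cosine


def build_catalog(muts: MutationTable, samples: list[str]) -> MutationCatalog:
    """Count qualifying SNVs per channel per sample.

    Non-SNVs and variants without a context are skipped (count logged);
    every qualifying SNV increments exactly one channel.
    """
    known = set(samples)
    bad = set(muts.records["sample_id"]) - known
    if bad:
        raise ValueError(f"mutation samples absent from cohort: {sorted(bad)[:5]}")
    counts = pd.DataFrame(0, index=list(CHANNELS_96), columns=samples, dtype=int)
    snvs = muts.snvs()
    skipped = len(muts) - len(snvs)
    if skipped:
        log.info("build_catalog: skipped %d non-SNV/contextless variants", skipped)
    for _, r in snvs.iterrows():
        ch = channel_of(r["trinucleotide_context"], r["ref_allele"],
                        r["alt_allele"])
        counts.loc[ch, r["sample_id"]] += 1
    if counts.to_numpy().sum() == 0:
        log.warning("build_catalog: all-zero catalog (no qualifying SNVs)")
    return MutationCatalog(counts)


def _fit_nmf(V: np.ndarray, k: int, seed: int, max_iter: int,
             tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    model = NMF(n_components=k, init="random", solver="mu",
                beta_loss="frobenius", max_iter=max_iter, tol=tol,
                random_state=seed)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # max_iter convergence warnings
        W = model.fit_transform(V)
    H = model.components_
    err = float(np.linalg.norm(V - W @ H))
    return W, H, err


def factorize(catalog: MutationCatalog, K: int, n_restarts: int = 10,
              rng_seed: int = 0, max_iter: int = 5000,
              tol: float = 1e-6) -> SignatureDecomposition:
    """Best-of-restarts multiplicative-update NMF of the catalog.

    W columns are L1-normalized with the compensating scale folded into H;
    H columns are then normalized to per-sample exposure fractions.
    """
    V = catalog.counts.to_numpy(dtype=float)
    n_samples = V.shape[1]
    if K < 1 or K > min(96, n_samples):
        raise ValueError(f"K={K} outside [1, min(96, n_samples)]")
    if not (V.sum(axis=0) > 0).any():
        raise ValueError("all-zero catalog")
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_restarts)
    best = None
    for seed in seeds:
        W, H, err = _fit_nmf(V, K, int(seed % (2 ** 31)), max_iter, tol)
        if best is None or err < best[2]:
            best = (W, H, err)
    W, H, err = best
    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    W = W / colsum
    H = H * colsum[:, None]
    hsum = H.sum(axis=0)
    hsum[hsum == 0] = 1.0
    H = H / hsum
    sig_names = [f"S{i + 1}" for i in range(K)]
    return SignatureDecomposition(
        W=pd.DataFrame(W, index=list(CHANNELS_96), columns=sig_names),
        H=pd.DataFrame(H, index=sig_names, columns=catalog.sample_ids),
        K=K, reconstruction_error=err,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm signature in cosine similarity")
    return float(np.dot(a, b) / (na * nb))


def _restart_stability(V: np.ndarray, k: int, rng_seed: int,
                       n_restarts: int, max_iter: int) -> float:
    """Mean within-k cosine of matched signatures across restarts."""
    seeds = np.random.SeedSequence((rng_seed, k)).generate_state(n_restarts)
    Ws = []
    for seed in seeds:
        W, _, _ = _fit_nmf(V, k, int(seed % (2 ** 31)), max_iter, 1e-5)
        norms = np.linalg.norm(W, axis=0)
        norms[norms == 0] = 1.0
        Ws.append(W / norms)
    if k == 1 or len(Ws) < 2:
        sims = [float(Ws[0][:, 0] @ w[:, 0]) for w in Ws[1:]] or [1.0]
        return float(np.mean(sims))
    ref = Ws[0]
    sims = []
    for W in Ws[1:]:
        C = ref.T @ W
        ri, ci = linear_sum_assignment(-C)
        sims.extend(C[ri, ci])
    return float(np.mean(sims))


def select_k(catalog: MutationCatalog, k_range, rng_seed: int = 0,
             elbow_threshold: float = 0.05, stability_threshold: float = 0.8,
             n_restarts: int = 2, max_iter: int = 600,
             null_ratio: float = 2.0) -> int:
    """Noise-calibrated elbow choice of the number of signatures.

    Scans ``k_range`` in ascending order.  The step to k is accepted only
    if the relative reconstruction-error improvement over k-1 exceeds both
    ``elbow_threshold`` and ``null_ratio`` times the improvement measured
    on a parametric-bootstrap null catalog (counts resampled from the
    rank-(k-1) fit, so the null carries the same heteroscedastic count
    noise but no k-th component).  The chosen k must additionally be
    stable across restarts (mean within-k matched cosine >=
    ``stability_threshold``).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    V = catalog.counts.to_numpy(dtype=float)
    col_tot = V.sum(axis=0)
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 9173)))

    def best_fit(k: int, M: np.ndarray, salt: int):
        seeds = np.random.SeedSequence((rng_seed, salt, k)).generate_state(
            max(1, n_restarts))
        best = None
        for s in seeds:
            fit = _fit_nmf(M, k, int(s % (2 ** 31)), max_iter, 1e-5)
            if best is None or fit[2] < best[2]:
                best = fit
        return best

    def null_catalog(W: np.ndarray, H: np.ndarray) -> np.ndarray:
        mean = W @ H
        Vn = np.zeros_like(V)
        for j in range(V.shape[1]):
            p = np.maximum(mean[:, j], 1e-12)
            Vn[:, j] = rng.multinomial(int(col_tot[j]), p / p.sum())
        return Vn

    chosen = ks[0]
    prev = best_fit(ks[0], V, 1)
    for k in ks[1:]:
        cur = best_fit(k, V, 1)
        improvement = (prev[2] - cur[2]) / prev[2] if prev[2] > 0 else 0.0
        Vn = null_catalog(prev[0], prev[1])
        n_prev = best_fit(k - 1, Vn, 2)
        n_cur = best_fit(k, Vn, 3)
        null_improvement = ((n_prev[2] - n_cur[2]) / n_prev[2]
                            if n_prev[2] > 0 else 0.0)
        if improvement < max(elbow_threshold, null_ratio * null_improvement):
            break
        chosen, prev = k, cur
    while chosen > ks[0] and _restart_stability(
            V, chosen, rng_seed, max(2, n_restarts),
            max_iter) < stability_threshold:
        chosen -= 1
    return chosen


def match_to_reference(W: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Arg-max-cosine reference match for each extracted signature."""
    if list(W.index) != list(CHANNELS_96) or list(reference.index) != list(CHANNELS_96):
        raise ValueError("W and reference must use the canonical 96 ordering")
    rows = []
    for sig in W.columns:
        w = W[sig].to_numpy(dtype=float)
        sims = {ref: cosine_similarity(w, reference[ref].to_numpy(dtype=float))
                for ref in reference.columns}
        best = max(sims, key=sims.get)
        rows.append({"signature": sig, "reference": best,
                     "cosine": sims[best]})
    return pd.DataFrame(rows)
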