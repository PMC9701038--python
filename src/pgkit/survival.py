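"""Survival statistics: Kaplan-Meier, log-rank, maxstat cutpoints, Cox.

The maximally-selected-rank-statistic cutpoint scans candidate thresholds
(observed values inside a quantile window) for the one maximizing the
absolute standardized log-rank score statistic, with a selection-adjusted
permutation p-value (the maximum statistic is recomputed on every
permutation of the feature values).  KM estimation, log-rank tests and
univariate Cox regression (Efron tie handling) are delegated to lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .io import OmicsMatrix, ClinicalTable
from .diffexp import bh_adjust

log = logging.getLogger(__name__)


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate at event times.

    Returns a frame with columns ``time``, ``at_risk``, ``events``,
    ``survival`` (one row per distinct observed time).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival data")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "time": tab.index.to_numpy(dtype=float),
        "at_risk": tab["at_risk"].to_numpy(dtype=int),
        "events": tab["observed"].to_numpy(dtype=int),
        "survival": surv.reindex(tab.index).to_numpy(dtype=float),
    }).reset_index(drop=True)
    return out


def km_survival_at(times, events, grid) -> np.ndarray:
    """KM survival probability evaluated on an arbitrary time grid."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    return kmf.survival_function_at_times(np.asarray(grid, dtype=float)
                                          ).to_numpy(dtype=float)


def logrank(times, events, groups) -> tuple[float, int, float]:
    """Multi-group log-rank test: ``(chi2, df, p)``."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    if events.sum() == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), int(uniq.size - 1), float(res.p_value)


# ---------------------------------------------------------------------------
# maximally selected rank statistics
# ---------------------------------------------------------------------------


def logrank_scores(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Per-subject log-rank (Savage-type) scores: event indicator minus the
    Nelson-Aalen cumulative hazard at the subject's time."""
    order = np.argsort(times, kind="mergesort")
    t_sorted = times[order]
    e_sorted = events[order]
    n = times.size
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    at_risk = n - first_idx
    d = np.add.reduceat(e_sorted, first_idx)
    cumhaz = np.cumsum(d / at_risk)
    haz_at = dict(zip(uniq, cumhaz))
    return events - np.array([haz_at[t] for t in times])


def _standardized_cut_stats(scores: np.ndarray, order: np.ndarray,
                            boundaries: np.ndarray) -> np.ndarray:
    """Z for each candidate boundary (group = first b subjects in x-order)."""
    n = scores.size
    a = scores - scores.mean()
    s2 = float((a ** 2).mean())
    csum = np.cumsum(a[order])
    n1 = boundaries.astype(float)
    var = n1 * (n - n1) / (n - 1.0) * s2
    with np.errstate(invalid="ignore", divide="ignore"):
        return csum[boundaries - 1] / np.sqrt(var)


@dataclass
class MaxstatResult:
    cutpoint: float
    statistic: float
    p: float
    n_candidates: int


def maxstat_cutpoint(feature_values, times, events, q_low: float = 0.1,
                     q_high: float = 0.9, n_perm: int = 1000,
                     rng_seed: int = 0, min_group: int = 10) -> MaxstatResult:
    """Optimal survival cutpoint by maximally selected rank statistics."""
    x = np.asarray(feature_values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ok = ~np.isnan(x)
    x, times, events = x[ok], times[ok], events[ok]
    n = x.size
    if n == 0 or np.unique(x).size < 2:
        raise ValueError("constant or empty feature")
    if events.sum() == 0:
        raise ValueError("no events observed")
    lo, hi = np.quantile(x, [q_low, q_high])
    order = np.argsort(x, kind="mergesort")
    x_sorted = x[order]
    # boundary b: low group = subjects with x <= cut value x_sorted[b-1]
    uniq_vals, last_pos = np.unique(x_sorted, return_index=True)
    counts = np.diff(np.append(last_pos, n))
    bounds_all = np.cumsum(counts)            # group sizes at each unique value
    keep = ((uniq_vals >= lo) & (uniq_vals <= hi)
            & (bounds_all >= min_group) & (n - bounds_all >= min_group))
    boundaries = bounds_all[keep]
    cut_vals = uniq_vals[keep]
    if boundaries.size == 0:
        raise ValueError("no candidate cutpoint leaves both sides populated")

    scores = logrank_scores(times, events)
    z = _standardized_cut_stats(scores, order, boundaries)
    best = int(np.argmax(np.abs(z)))
    observed = float(np.abs(z[best]))
    below = cut_vals[best]
    above = uniq_vals[np.searchsorted(uniq_vals, below, side="right")]
    cut = float((below + above) / 2.0)

    rng = np.random.default_rng(rng_seed)
    a = scores - scores.mean()
    s2 = float((a ** 2).mean())
    n1 = boundaries.astype(float)
    sd = np.sqrt(n1 * (n - n1) / (n - 1.0) * s2)
    perm = rng.permuted(np.tile(a, (n_perm, 1)), axis=1)
    csum = np.cumsum(perm, axis=1)[:, boundaries - 1]
    max_abs = np.abs(csum / sd).max(axis=1)
    p = float((1 + np.sum(max_abs >= observed - 1e-12)) / (n_perm + 1))
    return MaxstatResult(cutpoint=cut, statistic=observed, p=p,
                         n_candidates=int(boundaries.size))


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    converged: bool = True
    note: str = ""


def cox_univariate(covariate, times, events, min_events: int = 5) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald CI/p)."""
    x = np.asarray(covariate, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ok = ~np.isnan(x)
    x, times, events = x[ok], times[ok], events[ok]
    if np.unique(x).size < 2:
        raise ValueError("constant covariate")
    if events.sum() < min_events:
        raise ValueError(f"fewer than {min_events} events")
    df = pd.DataFrame({"x": x, "time": times, "event": events})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        return CoxResult(hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                         n=len(df), n_events=int(events.sum()),
                         converged=False, note=str(exc))
    s = cph.summary.loc["x"]
    return CoxResult(hr=float(s["exp(coef)"]),
                     ci_low=float(s["exp(coef) lower 95%"]),
                     ci_high=float(s["exp(coef) upper 95%"]),
                     p=float(s["p"]), n=len(df), n_events=int(events.sum()))


# ---------------------------------------------------------------------------
# per-feature screen
# ---------------------------------------------------------------------------


def survival_screen(matrix: OmicsMatrix, clinical: ClinicalTable,
                    endpoint: str = "os", q_low: float = 0.1,
                    q_high: float = 0.9, n_perm: int = 200,
                    rng_seed: int = 0, min_group: int = 10,
                    min_events: int = 5) -> pd.DataFrame:
    """Maxstat dichotomy + log-rank + Cox HR per feature; BH across features.

    Tumor samples only; features whose cutpoint scan or Cox fit fails are
    skipped (count logged).  Columns: cutpoint, hr, statistic, p, q, n.
    """
    if endpoint not in ("os", "dfs"):
        raise ValueError("endpoint must be 'os' or 'dfs'")
    tumors = clinical.tumors().set_index("sample_id")
    shared = [s for s in matrix.values.columns if s in tumors.index]
    times = tumors.loc[shared, f"{endpoint}_time"].to_numpy(dtype=float)
    events = tumors.loc[shared, f"{endpoint}_event"].to_numpy(dtype=int)
    rows, skipped = [], 0
    ss = np.random.SeedSequence(rng_seed)
    for feat, child in zip(matrix.values.index,
                           ss.spawn(len(matrix.values.index))):
        x = matrix.values.loc[feat, shared].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        try:
            if events[ok].sum() < min_events:
                raise ValueError("too few events")
            ms = maxstat_cutpoint(x[ok], times[ok], events[ok], q_low=q_low,
                                  q_high=q_high, n_perm=n_perm,
                                  rng_seed=int(child.generate_state(1)[0]
                                               % (2 ** 31)),
                                  min_group=min_group)
            high = (x[ok] > ms.cutpoint).astype(int)
            cox = cox_univariate(high, times[ok], events[ok],
                                 min_events=min_events)
            rows.append({"feature": feat, "cutpoint": ms.cutpoint,
                         "statistic": ms.statistic, "hr": cox.hr,
                         "ci_low": cox.ci_low, "ci_high": cox.ci_high,
                         "p": ms.p, "cox_p": cox.p, "n": int(ok.sum())})
        except ValueError:
            skipped += 1
    if skipped:
        log.info("survival_screen: %d features skipped", skipped)
    out = pd.DataFrame(rows, columns=["feature", "cutpoint", "statistic",
                                      "hr", "ci_low", "ci_high", "p",
                                      "cox_p", "n"])
    if len(out):
        out = out.set_index("feature")
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    out.attrs["skipped"] = skipped
    return out
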