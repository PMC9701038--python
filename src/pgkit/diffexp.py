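"""Differential-expression tests and biomarker filter cascades.

Two-group contrasts (Welch t by default, or Wilcoxon rank-sum) and
multi-group contrasts (one-way ANOVA / Kruskal-Wallis) with
Benjamini-Hochberg control; calls require both a fold-change and an
adjusted-p threshold.  Fold changes are computed on the linear scale
(log2-scale matrices are exponentiated first), then reported as log2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OmicsMatrix

log = logging.getLogger(__name__)

TESTS = ("t", "wilcoxon", "anova", "kruskal")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def zscore_rows(matrix: OmicsMatrix) -> OmicsMatrix:
    """Row-wise z-transform across samples (population-SD convention).

    Constant rows become all-missing (logged); missing cells stay missing.
    The transform is idempotent.
    """
    vals = matrix.values.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel() | ~np.isfinite(sd.ravel())
    if flat.any():
        log.info("zscore_rows: %d constant rows set to missing", flat.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[flat, :] = np.nan
    return OmicsMatrix(pd.DataFrame(z, index=matrix.values.index,
                                    columns=matrix.values.columns),
                       layer=matrix.layer, scale="zscore")


@dataclass
class DifferentialResult:
    table: pd.DataFrame          # per-feature stats
    test: str
    groups: list[str]
    skipped: list[str]           # features below min_obs

    def called(self, direction: str | None = None) -> pd.DataFrame:
        t = self.table
        if direction is None:
            return t[t["call"] != "ns"]
        return t[t["call"] == direction]


def _two_group_stat(a: np.ndarray, b: np.ndarray, test: str,
                    welch: bool) -> tuple[float, float]:
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=not welch)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"{test!r} is not a two-group test")
    return float(res.statistic), float(res.pvalue)


def compare_groups(matrix: OmicsMatrix, groups: pd.Series, test: str = "t",
                   fc_thresh: float = 2.0, q_thresh: float = 0.05,
                   min_obs: int | None = None, welch: bool = True,
                   use_adjusted: bool = True) -> DifferentialResult:
    """Per-feature differential test between sample groups.

    ``groups`` maps sample_id -> group label.  Two-group tests report the
    linear fold change first/second group (label-sorted order unless the
    Series' categorical order says otherwise); features with fewer than
    ``min_obs`` non-missing observations in any group are skipped and
    logged.  Calls need both ``|FC| >= fc_thresh`` and q (or raw p when
    ``use_adjusted=False``) below ``q_thresh``.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}")
    groups = groups.dropna()
    groups = groups[groups.index.isin(matrix.values.columns)]
    if isinstance(groups.dtype, pd.CategoricalDtype):
        labels = [l for l in groups.cat.categories if (groups == l).any()]
    else:
        labels = sorted(pd.unique(groups), key=str)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if test in ("t", "wilcoxon") and len(labels) != 2:
        raise ValueError(f"{test} requires exactly 2 groups")
    cols = {lab: groups.index[groups == lab] for lab in labels}
    for lab, ids in cols.items():
        if len(ids) == 0:
            raise ValueError(f"group {lab!r} is empty")
    if min_obs is None:
        min_obs = max(3, math.ceil(0.3 * min(len(v) for v in cols.values())))

    linear = matrix.to_linear()
    raw = matrix.values
    rows, skipped = [], []
    for feat in raw.index:
        obs = {lab: raw.loc[feat, ids].dropna() for lab, ids in cols.items()}
        if any(len(v) < min_obs for v in obs.values()):
            skipped.append(feat)
            continue
        lin_means = {lab: float(linear.loc[feat, v.index].mean())
                     for lab, v in obs.items()}
        if len(labels) == 2:
            a, b = (obs[labels[0]].to_numpy(dtype=float),
                    obs[labels[1]].to_numpy(dtype=float))
            stat, p = _two_group_stat(a, b, test, welch)
            denom = lin_means[labels[1]]
            fc = lin_means[labels[0]] / denom if denom > 0 else np.inf
            l2fc = np.log2(fc) if fc > 0 else -np.inf
        else:
            arrays = [obs[lab].to_numpy(dtype=float) for lab in labels]
            if test == "anova":
                res = stats.f_oneway(*arrays)
            elif test == "kruskal":
                res = stats.kruskal(*arrays)
            else:
                raise ValueError(f"{test} requires exactly 2 groups")
            stat, p = float(res.statistic), float(res.pvalue)
            fc, l2fc = np.nan, np.nan
        row = {"feature": feat, "statistic": stat, "p": p,
               "fc": fc, "log2fc": l2fc}
        for lab in labels:
            row[f"mean_{lab}"] = lin_means[lab]
        rows.append(row)
    if skipped:
        log.info("compare_groups: skipped %d features below min_obs=%d",
                 len(skipped), min_obs)
    table = pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
        columns=["statistic", "p", "fc", "log2fc", "q", "call"])
    if len(table):
        p_for_call = table["p"].to_numpy()
        if np.isnan(p_for_call).any():
            p_clean = np.nan_to_num(p_for_call, nan=1.0)
        else:
            p_clean = p_for_call
        table["q"] = bh_adjust(p_clean)
        crit = table["q"] if use_adjusted else table["p"]
        l2 = np.log2(fc_thresh)
        call = np.where(
            (crit < q_thresh) & (table["log2fc"] >= l2), "up",
            np.where((crit < q_thresh) & (table["log2fc"] <= -l2),
                     "down", "ns"))
        if len(labels) > 2:
            call = np.where(crit < q_thresh, "sig", "ns")
        table["call"] = call
    return DifferentialResult(table=table, test=test,
                              groups=[str(l) for l in labels], skipped=skipped)


# ---------------------------------------------------------------------------
# biomarker cascades
# ---------------------------------------------------------------------------


@dataclass
class CascadeResult:
    stages: list[str]
    counts: list[int]
    survivors: list[list[str]]

    @property
    def final(self) -> list[str]:
        return self.survivors[-1] if self.survivors else []


def biomarker_cascade_exosome(tumor_protein: OmicsMatrix,
                              nat_protein: OmicsMatrix,
                              survival_results: pd.DataFrame,
                              fc_thresh: float = 2.0,
                              p_thresh: float = 0.05,
                              use_adjusted: bool = False) -> CascadeResult:
    """Three-stage circulating-biomarker screen.

    (1) proteins quantified in 100% of tumor samples; (2) tumor-vs-NAT fold
    change > ``fc_thresh`` at raw p < ``p_thresh`` (adjusted-p mode behind
    the flag); (3) hazardous at the optimal survival cutpoint (HR > 1,
    log-rank p < 0.05 from ``survival_results`` indexed by feature with
    columns ``hr`` and ``p``).
    """
    if survival_results is None or not {"hr", "p"} <= set(
            survival_results.columns):
        raise ValueError("survival_results with 'hr' and 'p' columns required")
    complete = [f for f in tumor_protein.values.index
                if not tumor_protein.values.loc[f].isna().any()]
    stage1 = complete

    stage2: list[str] = []
    if stage1:
        merged = pd.concat([tumor_protein.values.loc[stage1],
                            nat_protein.values.loc[
                                [f for f in stage1
                                 if f in nat_protein.values.index]]],
                           axis=1, keys=["tumor", "nat"])
        sub = OmicsMatrix(merged.droplevel(0, axis=1).set_axis(
            [f"{k}:{c}" for k, c in merged.columns], axis=1),
            layer="protein", scale=tumor_protein.scale)
        labels = pd.Series(pd.Categorical(
            [c.split(":", 1)[0] for c in sub.values.columns],
            categories=["tumor", "nat"]), index=sub.values.columns)
        res = compare_groups(sub, labels, test="t", fc_thresh=fc_thresh,
                             q_thresh=p_thresh, use_adjusted=use_adjusted)
        crit = res.table["q"] if use_adjusted else res.table["p"]
        up = res.table[(res.table["fc"] > fc_thresh) & (crit < p_thresh)]
        stage2 = [f for f in stage1 if f in up.index]

    fits = survival_results.reindex(stage2).dropna(subset=["hr", "p"])
    stage3 = list(fits[(fits["hr"] > 1.0) & (fits["p"] < 0.05)].index)
    return CascadeResult(
        stages=["complete_in_tumors", "differential_vs_nat", "hazardous"],
        counts=[len(stage1), len(stage2), len(stage3)],
        survivors=[stage1, stage2, stage3])


def subtype_marker_screen(protein: OmicsMatrix, subtype_labels: pd.Series,
                          survival_results: pd.DataFrame,
                          detect_frac: float = 0.9, ratio_thresh: float = 1.5,
                          q_thresh: float = 0.05,
                          prognosis_p: float = 0.05) -> pd.DataFrame:
    """Subtype-discriminative marker screen (one-vs-rest contrasts).

    Markers must be (1) quantified in >= ``detect_frac`` of samples,
    (2) higher in one subtype than the rest (linear ratio >
    ``ratio_thresh``, BH-adjusted p < ``q_thresh``), and (3) prognostic
    (``survival_results['p'] < prognosis_p``).
    """
    labels = subtype_labels.dropna()
    labels = labels[labels.index.isin(protein.values.columns)]
    uniq = sorted(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 subtype labels")
    for lab in uniq:
        if (labels == lab).sum() < 3:
            raise ValueError(f"subtype {lab!r} has < 3 samples")
    mat = protein.subset_samples(labels.index)
    frac = mat.values.notna().mean(axis=1)
    detected = frac[frac >= detect_frac].index
    rows = []
    for lab in uniq:
        ovr = pd.Series(pd.Categorical(
            np.where(labels == lab, "this", "rest"),
            categories=["this", "rest"]), index=labels.index)
        res = compare_groups(
            OmicsMatrix(mat.values.loc[detected], protein.layer, mat.scale),
            ovr, test="t", fc_thresh=ratio_thresh, q_thresh=q_thresh)
        hits = res.table[(res.table["fc"] > ratio_thresh)
                         & (res.table["q"] < q_thresh)]
        for feat in hits.index:
            rows.append({"feature": feat, "subtype": lab,
                         "ratio": hits.loc[feat, "fc"],
                         "q": hits.loc[feat, "q"]})
    markers = pd.DataFrame(rows, columns=["feature", "subtype", "ratio", "q"])
    if len(markers):
        fits = survival_results.reindex(markers["feature"])
        markers["survival_p"] = fits["p"].to_numpy()
        markers = markers[markers["survival_p"] < prognosis_p]
    return markers.reset_index(drop=True)
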