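"""Copy-number cis/trans effect screening and genomic-event association tests.

A copy-number alteration correlating with expression of its own gene is a
cis-effect; with another gene's expression, a trans-effect (phosphosites
map to genes via their ID prefix).  Event co-occurrence / mutual
exclusivity uses the two-sided Fisher exact test (sum of hypergeometric
point probabilities no larger than the observed table's).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsMatrix, gene_of_feature
from .diffexp import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class CisTransResult:
    table: pd.DataFrame   # cna_gene, target_feature, layer, relation, rho, p, q, n_pairs


def cis_trans_screen(cna: OmicsMatrix, targets: OmicsMatrix,
                     mode: str = "cis_only", min_pairs: int = 10,
                     alternative: str = "two-sided",
                     positive_only: bool = True) -> CisTransResult:
    """Spearman screen of CNA values against a target layer.

    ``mode='cis_only'`` tests each CNA gene against its own-gene features
    only; ``mode='all'`` tests every (CNA gene, target feature) pair and
    labels each as cis or trans.  Correlations use pairwise-complete
    samples; BH is applied within the target layer.  ``positive_only``
    restricts the significance call column to positive correlations.
    """
    if mode not in ("cis_only", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    shared = [s for s in cna.values.columns if s in set(targets.values.columns)]
    if len(shared) < min_pairs:
        raise ValueError("no (or too few) shared samples between layers")
    cna_vals = cna.values[shared]
    tgt_vals = targets.values[shared]
    target_gene = {f: gene_of_feature(str(f)) for f in tgt_vals.index}

    if mode == "cis_only":
        by_gene: dict[str, list] = {}
        for f, g in target_gene.items():
            by_gene.setdefault(g, []).append(f)
        pairs = [(g, f) for g in cna_vals.index for f in by_gene.get(g, [])]
    else:
        pairs = [(g, f) for g in cna_vals.index for f in tgt_vals.index]

    rows, skipped = [], 0
    for g, f in pairs:
        x = cna_vals.loc[g]
        y = tgt_vals.loc[f]
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < min_pairs:
            skipped += 1
            continue
        rho, p = stats.spearmanr(x[ok], y[ok], alternative=alternative)
        rows.append({"cna_gene": g, "target_feature": f,
                     "target_layer": targets.layer,
                     "relation": "cis" if target_gene[f] == g else "trans",
                     "rho": float(rho), "p": float(p), "n_pairs": n})
    if skipped:
        log.info("cis_trans_screen: %d pairs skipped below min_pairs=%d",
                 skipped, min_pairs)
    table = pd.DataFrame(rows, columns=["cna_gene", "target_feature",
                                        "target_layer", "relation", "rho",
                                        "p", "n_pairs"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        sig = table["q"] < 0.05
        if positive_only:
            sig &= table["rho"] > 0
        table["significant"] = sig
    else:
        table["q"] = []
        table["significant"] = []
    return CisTransResult(table=table)


# ---------------------------------------------------------------------------
# event matrices and Fisher tests
# ---------------------------------------------------------------------------


@dataclass
class EventMatrix:
    """Binary events x samples (mutations, focal amps, arm deletions)."""

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if not np.isin(vals[~pd.isna(vals)], [0, 1]).all():
            raise ValueError("event matrix entries must be 0/1")
        self.values = self.values.astype(float).fillna(0).astype(int)


def _fisher_2x2(table: np.ndarray, ) -> tuple[float, float]:
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def mutual_exclusivity(events: EventMatrix, a: str, b: str
                       ) -> tuple[float, float, str]:
    """Two-sided Fisher exact test of co-occurrence between two events.

    Returns ``(odds_ratio, p, direction)`` with direction ``'exclusive'``
    for OR < 1, ``'co-occurring'`` for OR > 1, ``'independent'`` otherwise.
    """
    x = events.values.loc[a].to_numpy()
    y = events.values.loc[b].to_numpy()
    for name, v in ((a, x), (b, y)):
        if v.sum() == 0 or v.sum() == len(v):
            raise ValueError(f"event {name!r} has a degenerate margin")
    table = np.array([[np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
                      [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))]])
    odds, p = _fisher_2x2(table)
    direction = ("exclusive" if odds < 1.0
                 else "co-occurring" if odds > 1.0 else "independent")
    return odds, p, direction


def event_feature_association(events: EventMatrix, feature_table: pd.DataFrame,
                              unknown_labels: tuple = ("unknown", "Not sure"),
                              ) -> pd.DataFrame:
    """Batched Fisher tests of each event against each clinical category.

    Clinical columns must be dichotomous after excluding missing values and
    ``unknown_labels`` (excluded counts are reported); BH across all tested
    pairs.
    """
    rows = []
    for col in feature_table.columns:
        lab = feature_table[col].replace(list(unknown_labels), np.nan).dropna()
        levels = sorted(pd.unique(lab).astype(str))
        if len(levels) < 2:
            continue
        if len(levels) > 2:
            raise ValueError(
                f"column {col!r} has unexpected category levels: {levels}")
        n_excluded = len(feature_table) - len(lab)
        shared = [s for s in events.values.columns if s in set(lab.index)]
        y = (lab.loc[shared].astype(str) == levels[1]).astype(int).to_numpy()
        for ev in events.values.index:
            x = events.values.loc[ev, shared].to_numpy()
            if x.sum() in (0, len(x)) or y.sum() in (0, len(y)):
                continue
            table = np.array([[np.sum((x == 1) & (y == 1)),
                               np.sum((x == 1) & (y == 0))],
                              [np.sum((x == 0) & (y == 1)),
                               np.sum((x == 0) & (y == 0))]])
            odds, p = _fisher_2x2(table)
            rows.append({"event": ev, "variable": col, "odds_ratio": odds,
                         "p": p, "n": len(shared), "n_excluded": n_excluded})
    out = pd.DataFrame(rows, columns=["event", "variable", "odds_ratio", "p",
                                      "n", "n_excluded"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out
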