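"""Kinase-substrate enrichment (KSEA) and kinase-substrate correlation.

The KSEA statistic compares a kinase's substrate phosphosites against the
full-site background: ``z = (mean(S) - mean(all)) * sqrt(m) / sd(all)``
with ``m`` matched substrates, a two-sided normal p-value and BH control
across kinases.  Sites shared by several kinases count for each of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import KinaseSubstrateMap, OmicsMatrix, gene_of_feature
from .diffexp import bh_adjust, zscore_rows

log = logging.getLogger(__name__)


@dataclass
class KinaseActivityResult:
    table: pd.DataFrame          # kinase -> m, z, p, q, substrates
    skipped: list[str]           # kinases below min_substrates


def ksea_z(site_log2fc: pd.Series, ks_map: KinaseSubstrateMap,
           min_substrates: int = 3) -> KinaseActivityResult:
    """KSEA z-scores for one contrast vector of per-site log2 fold changes."""
    vec = site_log2fc.dropna().astype(float)
    if not np.all(np.isfinite(vec.to_numpy())):
        raise ValueError("non-finite site values")
    global_mean = float(vec.mean())
    global_sd = float(vec.std(ddof=0))
    if global_sd == 0:
        raise ValueError("zero variance across sites")
    rows, skipped = [], []
    for kinase in ks_map.kinases():
        matched = sorted(ks_map[kinase] & set(vec.index))
        m = len(matched)
        if m < min_substrates:
            skipped.append(kinase)
            continue
        z = (float(vec.loc[matched].mean()) - global_mean) * np.sqrt(m) / global_sd
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"kinase": kinase, "m": m, "z": z, "p": p,
                     "substrates": ",".join(matched)})
    if skipped:
        log.info("ksea_z: %d kinases below min_substrates=%d",
                 len(skipped), min_substrates)
    table = (pd.DataFrame(rows).set_index("kinase") if rows
             else pd.DataFrame(columns=["m", "z", "p", "q", "substrates"]))
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values("z", ascending=False)
    return KinaseActivityResult(table=table, skipped=skipped)


def ksea_per_sample(phospho: OmicsMatrix, ks_map: KinaseSubstrateMap,
                    min_substrates: int = 3) -> pd.DataFrame:
    """Per-sample KSEA: each sample's site z-scores fed through ``ksea_z``."""
    z = zscore_rows(phospho)
    out = {}
    for sample in z.values.columns:
        res = ksea_z(z.values[sample], ks_map, min_substrates=min_substrates)
        out[sample] = res.table["z"]
    return pd.DataFrame(out)


def contrast_log2fc(phospho: OmicsMatrix, tumor_ids, nat_ids) -> pd.Series:
    """Per-site tumor/NAT mean log2 fold change (log2-scale input)."""
    if phospho.scale != "log2":
        raise ValueError("contrast_log2fc expects a log2-scale matrix")
    t = phospho.values[list(tumor_ids)].mean(axis=1, skipna=True)
    n = phospho.values[list(nat_ids)].mean(axis=1, skipna=True)
    return (t - n).rename("log2fc")


def kinase_substrate_correlation(kinase_abundance: pd.Series,
                                 site_matrix: OmicsMatrix,
                                 ks_map: KinaseSubstrateMap,
                                 kinase: str | None = None,
                                 min_pairs: int = 10) -> pd.DataFrame:
    """Spearman correlation of a kinase's protein abundance with its substrates.

    ``kinase_abundance`` is one protein row (indexed by sample);
    ``kinase`` defaults to the gene symbol of that row's name.  Pairs with
    fewer than ``min_pairs`` complete observations are skipped (logged);
    BH across tested sites.
    """
    if kinase is None:
        kinase = gene_of_feature(str(kinase_abundance.name))
    if kinase not in ks_map.substrates:
        raise ValueError(f"kinase {kinase!r} absent from the substrate map")
    sites = sorted(ks_map[kinase] & set(site_matrix.values.index))
    rows, skipped = [], 0
    for site in sites:
        pair = pd.concat([kinase_abundance,
                          site_matrix.values.loc[site]], axis=1).dropna()
        if len(pair) < min_pairs:
            skipped += 1
            continue
        rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"site": site, "rho": float(rho), "p": float(p),
                     "n_pairs": len(pair)})
    if skipped:
        log.info("kinase_substrate_correlation: %d sites below %d pairs",
                 skipped, min_pairs)
    table = (pd.DataFrame(rows).set_index("site") if rows
             else pd.DataFrame(columns=["rho", "p", "q", "n_pairs"]))
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    return table
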