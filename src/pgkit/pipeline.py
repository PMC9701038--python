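"""End-to-end orchestration: simulate -> summary -> signatures -> diffexp ->
scores -> ksea -> cistrans -> subtype -> survival, from one config, with
provenance-stamped outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (ClinicalTable, OmicsMatrix, write_clinical, write_gmt,
                 write_ks_map, write_maf, write_matrix)
from .synthetic import Cohort, CohortConfig, generate_cohort
from .signatures import build_catalog, factorize, match_to_reference, select_k
from .diffexp import compare_groups
from .scoring import gsva_score
from .ksea import contrast_log2fc, ksea_z
from .cna import cis_trans_screen
from .subtyping import choose_k, consensus_cluster, select_features
from .survival import logrank, survival_screen

log = logging.getLogger(__name__)

STAGES = ("simulate", "summary", "signatures", "diffexp", "score", "ksea",
          "cistrans", "subtype", "survival")


def percentage(count: float, denom: float, decimals: int = 0) -> float:
    """Rendered percentage with the source's decimal convention."""
    if denom <= 0:
        raise ValueError("empty denominator")
    return round(100.0 * count / denom, decimals) if decimals else round(
        100.0 * count / denom)


def summarize_cohort(clinical: ClinicalTable | None = None,
                     counts: pd.Series | None = None,
                     variables: list[str] | None = None,
                     decimals: int = 0) -> pd.DataFrame:
    """Per-category counts and percentages (denominator = non-missing).

    Either a clinical table (categorical ``variables`` summarized per
    patient over tumor samples) or an explicit count table (category ->
    count) can be supplied.
    """
    rows = []
    if counts is not None:
        total = float(counts.sum())
        for cat, cnt in counts.items():
            rows.append({"variable": counts.name or "counts", "category": cat,
                         "count": int(cnt),
                         "pct": percentage(cnt, total, decimals)})
        return pd.DataFrame(rows)
    if clinical is None:
        raise ValueError("need a clinical table or a count table")
    tumors = clinical.tumors()
    if len(tumors) == 0:
        raise ValueError("empty clinical table")
    variables = variables or ["sex", "tnm_stage", "location", "diabetes",
                              "metastasis"]
    for var in variables:
        col = tumors[var].replace(["unknown", "Not sure"], np.nan)
        known = col.dropna()
        if known.empty:
            rows.append({"variable": var, "category": "(all missing)",
                         "count": 0, "pct": np.nan})
            continue
        denom = len(known)
        for cat, cnt in known.value_counts().sort_index().items():
            rows.append({"variable": var, "category": cat, "count": int(cnt),
                         "pct": percentage(cnt, denom, decimals)})
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    out_dir: str = "pgkit_out"
    rng_seed: int = 0
    stages: tuple = STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    nmf_k_range: tuple = (1, 2, 3, 4, 5)
    nmf_restarts: int = 3
    consensus_k_range: tuple = (2, 3, 4, 5)
    consensus_reps: int = 200
    survival_features: int = 30     # screened features (top-variance)
    survival_perm: int = 200
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        cfg = cls(cohort=cohort, **raw)
        return cfg


def _stamp(path: Path, stage: str, params: dict, df: pd.DataFrame,
           index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} version={__version__} "
                 + " ".join(f"{k}={v}" for k, v in params.items()) + "\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index=index)


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Run all enabled stages in dependency order; returns the provenance.

    Each output TSV carries a header comment with stage, parameters and
    seed; a ``provenance.json`` indexes every artifact.  A stage failure
    halts the run with the stage named; earlier outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    prov: dict = {"version": __version__, "rng_seed": seed, "artifacts": {},
                  "stages": []}
    enabled = set(config.stages)

    def register(stage: str, name: str, path: Path) -> None:
        prov["artifacts"][name] = str(path)
        if stage not in prov["stages"]:
            prov["stages"].append(stage)

    def run_stage(stage, fn):
        if stage not in enabled:
            return
        try:
            fn()
        except Exception as exc:
            _write_provenance()
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    def _write_provenance():
        with open(out / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2, sort_keys=True)

    # --- simulate ---------------------------------------------------------
    if cohort is None:
        config.cohort.rng_seed = seed
        cohort = generate_cohort(config.cohort)
    if "simulate" in enabled:
        write_clinical(cohort.clinical, out / "clinical.tsv")
        for name, layer in cohort.layers.items():
            write_matrix(layer, out / f"{name}.tsv")
            register("simulate", name, out / f"{name}.tsv")
        write_maf(cohort.mutations, out / "mutations.maf.tsv")
        write_gmt(cohort.gene_sets, out / "gene_sets.gmt")
        write_ks_map(cohort.ks_map, out / "ks_map.tsv")
        truth = {
            "subtype": cohort.truth.subtype.to_dict(),
            "immune_cluster": cohort.truth.immune_cluster.to_dict(),
            "cis_genes": cohort.truth.cis_genes.to_dict(),
            "biomarkers": cohort.truth.biomarkers,
            "active_kinases": cohort.truth.active_kinases.to_dict(),
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        register("simulate", "clinical", out / "clinical.tsv")
        register("simulate", "mutations", out / "mutations.maf.tsv")
        register("simulate", "truth", out / "truth.json")

    clinical = cohort.clinical
    tumor_ids = list(clinical.tumors()["sample_id"])
    nat_ids = list(clinical.nats()["sample_id"])
    protein = cohort.layers["protein"]
    tumor_protein = protein.subset_samples(
        [s for s in tumor_ids if s in protein.values.columns])

    # --- summary ----------------------------------------------------------
    def _summary():
        df = summarize_cohort(clinical)
        _stamp(out / "cohort_summary.tsv", "summary", {"seed": seed}, df,
               index=False)
        register("summary", "cohort_summary", out / "cohort_summary.tsv")
    run_stage("summary", _summary)

    # --- signatures --------------------------------------------------------
    def _signatures():
        catalog = build_catalog(cohort.mutations, tumor_ids)
        ks = [k for k in config.nmf_k_range
              if 1 <= k <= min(96, len(tumor_ids))]
        k = select_k(catalog, ks, rng_seed=seed,
                     n_restarts=config.nmf_restarts)
        dec = factorize(catalog, k, n_restarts=config.nmf_restarts,
                        rng_seed=seed, max_iter=1000)
        dec.matches = match_to_reference(dec.W, cohort.truth.signatures)
        params = {"seed": seed, "k": k}
        _stamp(out / "signatures_W.tsv", "signatures", params, dec.W)
        _stamp(out / "signatures_H.tsv", "signatures", params, dec.H)
        _stamp(out / "signature_matches.tsv", "signatures", params,
               dec.matches, index=False)
        register("signatures", "signatures_W", out / "signatures_W.tsv")
        register("signatures", "signature_matches",
                 out / "signature_matches.tsv")
    run_stage("signatures", _signatures)

    # --- diffexp -----------------------------------------------------------
    def _diffexp():
        tissue = clinical.tissue_of()
        res = compare_groups(protein, tissue.astype(
            pd.CategoricalDtype(["tumor", "nat"])))
        _stamp(out / "diffexp_protein.tsv", "diffexp",
               {"seed": seed, "test": res.test}, res.table)
        register("diffexp", "diffexp_protein", out / "diffexp_protein.tsv")
    run_stage("diffexp", _diffexp)

    # --- score -------------------------------------------------------------
    def _score():
        scores = gsva_score(tumor_protein, cohort.gene_sets)
        _stamp(out / "gsva_scores.tsv", "score", {"seed": seed}, scores)
        register("score", "gsva_scores", out / "gsva_scores.tsv")
    run_stage("score", _score)

    # --- ksea --------------------------------------------------------------
    def _ksea():
        phospho = cohort.layers["phospho"]
        fc = contrast_log2fc(phospho, tumor_ids, nat_ids)
        res = ksea_z(fc, cohort.ks_map)
        _stamp(out / "ksea.tsv", "ksea", {"seed": seed}, res.table)
        register("ksea", "ksea", out / "ksea.tsv")
    run_stage("ksea", _ksea)

    # --- cistrans ----------------------------------------------------------
    def _cistrans():
        res = cis_trans_screen(cohort.layers["cna"], tumor_protein,
                               mode="cis_only")
        _stamp(out / "cis_trans.tsv", "cistrans", {"seed": seed}, res.table,
               index=False)
        register("cistrans", "cis_trans", out / "cis_trans.tsv")
    run_stage("cistrans", _cistrans)

    # --- subtype -----------------------------------------------------------
    assignments = None

    def _subtype():
        nonlocal assignments
        feats = select_features(tumor_protein, 0.5)
        sub = OmicsMatrix(tumor_protein.values.loc[feats], protein.layer,
                          protein.scale)
        res = consensus_cluster(sub, config.consensus_k_range,
                                n_reps=config.consensus_reps, rng_seed=seed)
        k = choose_k(res)
        assignments = res.assignments[k]
        diag = pd.DataFrame({
            "k": res.k_range,
            "area": [res.area[k_] for k_ in res.k_range],
            "delta_area": [res.delta_area[k_] for k_ in res.k_range],
            "silhouette": [res.silhouette[k_] for k_ in res.k_range],
        })
        params = {"seed": seed, "chosen_k": k, "confident": res.confident}
        _stamp(out / "subtype_assignments.tsv", "subtype", params,
               assignments.rename("subtype").to_frame())
        _stamp(out / "subtype_diagnostics.tsv", "subtype", params, diag,
               index=False)
        register("subtype", "subtype_assignments",
                 out / "subtype_assignments.tsv")
        register("subtype", "subtype_diagnostics",
                 out / "subtype_diagnostics.tsv")
    run_stage("subtype", _subtype)

    # --- survival ----------------------------------------------------------
    def _survival():
        feats = select_features(tumor_protein, 1.0)[:config.survival_features]
        sub = OmicsMatrix(tumor_protein.values.loc[feats], protein.layer,
                          protein.scale)
        fits = survival_screen(sub, clinical, endpoint="os",
                               n_perm=config.survival_perm, rng_seed=seed)
        _stamp(out / "survival_screen.tsv", "survival",
               {"seed": seed, "endpoint": "os"}, fits)
        register("survival", "survival_screen", out / "survival_screen.tsv")
        if assignments is not None:
            tumors = clinical.tumors().set_index("sample_id")
            shared = [s for s in assignments.index if s in tumors.index]
            chi2, df_, p = logrank(tumors.loc[shared, "os_time"],
                                   tumors.loc[shared, "os_event"],
                                   assignments.loc[shared])
            _stamp(out / "subtype_survival.tsv", "survival", {"seed": seed},
                   pd.DataFrame([{"chi2": chi2, "df": df_, "p": p}]),
                   index=False)
            register("survival", "subtype_survival",
                     out / "subtype_survival.tsv")
    run_stage("survival", _survival)

    _write_provenance()
    register_path = out / "provenance.json"
    prov["artifacts"]["provenance"] = str(register_path)
    _write_provenance()
    return prov
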