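"""Synthetic paired tumor/NAT multi-omics cohorts with recorded ground truth.

The generator plants every structure the downstream stages are meant to
recover — tumor/NAT differential programs, cis-regulated genes, mixtures of
trinucleotide mutational signatures, proteomic subtypes, immune-score
clusters, active kinases, and subtype/marker-dependent survival — and
records it all in a :class:`CohortTruth` ledger.  One RNG stream per output
layer (all spawned from ``rng_seed``) keeps layers independent: adding a
layer never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .io import (
    CHANNELS_96,
    ClinicalTable,
    GeneSetCollection,
    KinaseSubstrateMap,
    MutationTable,
    OmicsMatrix,
)


class ConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Study-design knobs for a synthetic paired cohort.

    Defaults mirror a scaled-down version of a paired tumor/NAT
    proteogenomic study: ~30% of proteins up and ~11% down in tumors at a
    2-unit log2 effect, three proteomic subtypes on disjoint 100-gene
    programs shifted by 2 residual SDs, five immune clusters over 64 cell
    scores, three trinucleotide signatures, and exponential survival whose
    hazard depends on subtype and planted markers.
    """

    n_patients: int = 100
    n_genes: int = 1200
    n_phosphosites: int = 600
    n_mut_per_sample: float = 130.0
    k_signatures: int = 3
    signature_sparsity: float = 0.08

    frac_tumor_up: float = 0.30
    frac_tumor_down: float = 0.11
    effect_mean: float = 2.0
    effect_sd: float = 0.3

    n_cis_genes: int = 50
    cis_slope_mean: float = 0.8
    cis_slope_sd: float = 0.15
    cna_sd: float = 1.0

    n_subtypes: int = 3
    program_size: int = 100
    subtype_shift_sd: float = 2.0
    n_subtype_markers: int = 12  # per subtype, complete + prognostic
    marker_latent_sd: float = 0.8  # markers' loading on the prognostic factor

    n_immune_clusters: int = 5
    n_celltypes: int = 64
    immune_cluster_sd: float = 0.4

    n_active_kinases: int = 3
    n_null_kinases: int = 20
    substrates_per_kinase: int = 10
    kinase_substrate_shift: float = 1.5

    n_biomarkers: int = 10  # complete, strong-FC, hazardous proteins
    biomarker_log2fc: float = 2.0
    biomarker_latent_sd: float = 1.2   # loading on the aggressiveness factor
    biomarker_loghr: float = 1.2       # hazard per aggressiveness SD

    baseline_rate: float = 1.0 / 500.0  # events per day
    # distinct per-subtype baseline hazards so each subtype's markers carry
    # a marginal survival signal (the middle value must not sit at the mean
    # of the others)
    subtype_loghr: tuple = (1.4, -1.2, 1.2)
    censor_rate: float = 1.0 / 1500.0

    missing_rate_protein: float = 0.10
    missing_rate_phospho: float = 0.20

    rng_seed: int = 0

    def validate(self) -> None:
        positive = ["n_patients", "n_genes", "n_phosphosites", "k_signatures",
                    "n_subtypes", "n_immune_clusters", "n_celltypes"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ["frac_tumor_up", "frac_tumor_down",
                     "missing_rate_protein", "missing_rate_phospho"]:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.frac_tumor_up + self.frac_tumor_down > 1.0:
            raise ConfigError("frac_tumor_up + frac_tumor_down > 1")
        if self.baseline_rate <= 0:
            raise ConfigError("baseline_rate must be > 0")
        if self.n_subtypes > self.n_patients:
            raise ConfigError("n_subtypes > n_patients")
        needed = (self.n_subtypes * self.program_size + self.n_cis_genes
                  + self.n_biomarkers)
        if needed > self.n_genes:
            raise ConfigError(
                f"subtype programs + cis genes + biomarkers ({needed}) "
                f"exceed n_genes ({self.n_genes})")
        if len(self.subtype_loghr) < self.n_subtypes:
            raise ConfigError("subtype_loghr shorter than n_subtypes")


@dataclass
class CohortTruth:
    """Ledger of planted effects — the acceptance surface for every stage."""

    log2fc: pd.Series                      # per-gene tumor/NAT effect
    cis_genes: pd.Series                   # gene -> slope
    subtype: pd.Series                     # tumor sample -> 1..n_subtypes
    immune_cluster: pd.Series              # tumor sample -> 1..n_immune
    exposures: pd.DataFrame                # samples x K, rows sum to 1
    signatures: pd.DataFrame               # 96 x K, columns sum to 1
    linear_predictor: pd.Series            # tumor sample -> true log-hazard
    active_kinases: pd.Series              # kinase -> substrate shift
    programs: dict[str, set] = field(default_factory=dict)
    subtype_markers: dict[int, list] = field(default_factory=dict)
    biomarkers: list = field(default_factory=list)


@dataclass
class Cohort:
    clinical: ClinicalTable
    layers: dict[str, OmicsMatrix]
    mutations: MutationTable
    gene_sets: GeneSetCollection
    ks_map: KinaseSubstrateMap
    truth: CohortTruth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def simulate_survival(linear_predictors, baseline_rate: float,
                      censor_rate: float, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Proportional-hazards event times with independent exponential censoring.

    Event times are exponential with hazard ``baseline_rate * exp(lp)``;
    censoring times exponential with rate ``censor_rate`` (0 = none);
    ``event = 1`` iff the event precedes censoring.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictors")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    hazard = baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=lp.shape)
    else:
        t_cens = np.full(lp.shape, np.inf)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return times, events


# ---------------------------------------------------------------------------
# mutational signatures
# ---------------------------------------------------------------------------


def draw_signatures(k: int, sparsity: float, rng: np.random.Generator
                    ) -> np.ndarray:
    """Sparse Dirichlet signature matrix, 96 x k, columns sum to 1."""
    W = rng.dirichlet(np.full(96, sparsity), size=k).T
    return W / W.sum(axis=0, keepdims=True)


def simulate_catalog(n_samples: int, k: int, n_mut: float,
                     rng: np.random.Generator, sparsity: float = 0.08,
                     exposure_alpha: float = 1.0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """96 x n_samples count catalog from a planted signature mixture.

    Returns ``(counts, signatures, exposures)`` with signatures 96 x k
    (columns sum to 1) and exposures n_samples x k (rows sum to 1).
    """
    W = draw_signatures(k, sparsity, rng)
    E = rng.dirichlet(np.full(k, exposure_alpha), size=n_samples)
    counts = np.zeros((96, n_samples), dtype=int)
    for j in range(n_samples):
        m = rng.poisson(n_mut)
        p = W @ E[j]
        counts[:, j] = rng.multinomial(m, p / p.sum())
    return counts, W, E


def _catalog_to_mutation_records(counts: np.ndarray, sample_ids: list[str],
                                 genes: list[str], rng: np.random.Generator
                                 ) -> list[dict]:
    """Expand a 96-channel catalog into per-variant MAF-like records."""
    rows = []
    for j, sid in enumerate(sample_ids):
        for ch_idx in np.repeat(np.arange(96), counts[:, j]):
            ch = CHANNELS_96[ch_idx]
            five, rest = ch[0], ch[2:]
            ref, alt, three = rest[0], rest[2], rest[4]
            rows.append({
                "sample_id": sid,
                "gene": genes[rng.integers(len(genes))],
                "variant_class": "missense" if rng.random() < 0.94 else "nonsense",
                "ref_allele": ref,
                "alt_allele": alt,
                "trinucleotide_context": f"{five}{ref}{three}",
                "protein_change": None,
            })
        # a few indels without trinucleotide context
        for _ in range(rng.poisson(0.2 * counts[:, j].sum())):
            rows.append({
                "sample_id": sid,
                "gene": genes[rng.integers(len(genes))],
                "variant_class": "frameshift" if rng.random() < 0.5 else "inframe",
                "ref_allele": "A",
                "alt_allele": "-",
                "trinucleotide_context": None,
                "protein_change": None,
            })
    return rows


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


def _intensity_missing_mask(values: np.ndarray, rate: float,
                            rng: np.random.Generator) -> np.ndarray:
    """MS-like dropout: missingness probability decreasing in abundance."""
    if rate <= 0:
        return np.zeros(values.shape, dtype=bool)
    order = values.argsort(axis=None).argsort(axis=None)
    u = (order + 0.5) / values.size            # abundance percentile
    p = np.clip(2.0 * rate * (1.0 - u), 0.0, 0.95).reshape(values.shape)
    return rng.random(values.shape) < p


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full paired cohort; deterministic given ``config.rng_seed``."""
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ["design", "mrna", "protein", "phospho", "cna", "mutation",
         "cellscore", "survival", "clinical"],
        ss.spawn(9))}

    n = config.n_patients
    patients = [f"P{i + 1:04d}" for i in range(n)]
    tumor_ids = [f"{p}_T" for p in patients]
    nat_ids = [f"{p}_N" for p in patients]
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    rng = streams["design"]

    # --- planted design -----------------------------------------------------
    n_up = int(round(config.frac_tumor_up * config.n_genes))
    n_down = int(round(config.frac_tumor_down * config.n_genes))
    perm = rng.permutation(config.n_genes)
    up_idx, down_idx = perm[:n_up], perm[n_up:n_up + n_down]
    log2fc = np.zeros(config.n_genes)
    log2fc[up_idx] = np.abs(rng.normal(config.effect_mean, config.effect_sd, n_up))
    log2fc[down_idx] = -np.abs(rng.normal(config.effect_mean, config.effect_sd, n_down))
    log2fc_s = pd.Series(log2fc, index=genes, name="log2fc")

    # subtype programs: disjoint gene blocks, shifted in that subtype's tumors
    prog_pool = rng.permutation(config.n_genes)
    programs: dict[str, set] = {}
    subtype_markers: dict[int, list] = {}
    prog_idx = {}
    for s in range(config.n_subtypes):
        block = prog_pool[s * config.program_size:(s + 1) * config.program_size]
        prog_idx[s + 1] = block
        programs[f"PROGRAM_S{s + 1}"] = {genes[i] for i in block}
        subtype_markers[s + 1] = [genes[i]
                                  for i in block[:config.n_subtype_markers]]
    subtype = rng.integers(1, config.n_subtypes + 1, size=n)
    # guarantee every subtype occupied
    subtype[:config.n_subtypes] = np.arange(1, config.n_subtypes + 1)
    subtype_s = pd.Series(subtype, index=tumor_ids, name="subtype")

    # cis genes (disjoint from program blocks so effects stay separable)
    non_prog = prog_pool[config.n_subtypes * config.program_size:]
    cis_idx = non_prog[:config.n_cis_genes]
    slopes = rng.normal(config.cis_slope_mean, config.cis_slope_sd,
                        config.n_cis_genes)
    cis_s = pd.Series(slopes, index=[genes[i] for i in cis_idx], name="slope")

    # engineered biomarkers: complete, strong FC, hazardous.  They load on
    # one latent per-patient "aggressiveness" factor that also raises the
    # hazard, mimicking a co-expressed prognostic program.
    bio_idx = non_prog[config.n_cis_genes:
                       config.n_cis_genes + config.n_biomarkers]
    biomarkers = [genes[i] for i in bio_idx]
    log2fc_s.loc[biomarkers] = config.biomarker_log2fc
    aggressiveness = rng.normal(size=n)

    immune_cluster = rng.integers(1, config.n_immune_clusters + 1, size=n)
    immune_cluster[:config.n_immune_clusters] = np.arange(
        1, config.n_immune_clusters + 1)
    immune_s = pd.Series(immune_cluster, index=tumor_ids, name="immune_cluster")

    # --- CNA layer ----------------------------------------------------------
    cna_rng = streams["cna"]
    cna = cna_rng.normal(0.0, config.cna_sd, size=(config.n_genes, n))
    cna_df = pd.DataFrame(cna, index=genes, columns=tumor_ids)

    # --- expression layers (log2 Gaussian programs) -------------------------
    def expression(rng_l: np.random.Generator, noise_sd: float = 1.0
                   ) -> pd.DataFrame:
        base = rng_l.normal(6.0, 1.5, size=config.n_genes)
        tumor = base[:, None] + rng_l.normal(0, noise_sd, (config.n_genes, n))
        nat = base[:, None] + rng_l.normal(0, noise_sd, (config.n_genes, n))
        tumor += log2fc_s.to_numpy()[:, None]
        for s in range(1, config.n_subtypes + 1):
            cols = subtype == s
            tumor[np.ix_(prog_idx[s], cols)] += config.subtype_shift_sd * noise_sd
        tumor[cis_idx, :] += slopes[:, None] * cna[cis_idx, :]
        if len(bio_idx):
            tumor[bio_idx, :] += config.biomarker_latent_sd * aggressiveness
        # marker panels load on the prognostic factor, with the sign of
        # their subtype's hazard relative to the cohort (protective
        # programs anticorrelate with aggressiveness) so the group effect
        # and the latent effect reinforce instead of cancelling
        mean_loghr = float(np.mean(config.subtype_loghr[:config.n_subtypes]))
        for s in range(1, config.n_subtypes + 1):
            m_idx = [genes.index(g) for g in subtype_markers[s]]
            if not m_idx:
                continue
            sign = 1.0 if config.subtype_loghr[s - 1] >= mean_loghr else -1.0
            tumor[m_idx, :] += sign * config.marker_latent_sd * aggressiveness
        df = pd.DataFrame(np.hstack([tumor, nat]), index=genes,
                          columns=tumor_ids + nat_ids)
        return df

    protein_log2 = expression(streams["protein"])
    mrna_log2 = expression(streams["mrna"])

    # protein missingness (intensity-dependent), biomarkers kept complete
    mask = _intensity_missing_mask(protein_log2.to_numpy(),
                                   config.missing_rate_protein,
                                   streams["protein"])
    mask[[genes.index(g) for g in biomarkers], :] = False
    for s, marks in subtype_markers.items():
        mask[[genes.index(g) for g in marks], :] = False
    protein_vals = protein_log2.to_numpy().copy()
    protein_vals[mask] = np.nan
    protein = OmicsMatrix(pd.DataFrame(protein_vals, index=genes,
                                       columns=protein_log2.columns),
                          layer="protein", scale="log2")
    mrna = OmicsMatrix(2.0 ** mrna_log2, layer="mrna", scale="linear_nonneg")
    cna_m = OmicsMatrix(cna_df, layer="cna", scale="logratio")

    # --- phospho layer + kinase truth ---------------------------------------
    ph_rng = streams["phospho"]
    site_genes = [genes[ph_rng.integers(config.n_genes)]
                  for _ in range(config.n_phosphosites)]
    residues = ph_rng.choice(list("STY"), size=config.n_phosphosites,
                             p=[0.73, 0.24, 0.03])
    positions = ph_rng.integers(10, 2000, size=config.n_phosphosites)
    site_ids = []
    seen = set()
    for g, r, pos in zip(site_genes, residues, positions):
        sid = f"{g}_p{r}{pos}"
        while sid in seen:
            pos += 1
            sid = f"{g}_p{r}{pos}"
        seen.add(sid)
        site_ids.append(sid)

    parent = protein_log2.loc[site_genes].to_numpy()
    phospho_vals = parent + ph_rng.normal(0, 0.8, parent.shape)

    n_kin = config.n_active_kinases + config.n_null_kinases
    kin_names = [f"KIN{i + 1:03d}" for i in range(n_kin)]
    site_perm = ph_rng.permutation(config.n_phosphosites)
    substrates: dict[str, set] = {}
    for i, kin in enumerate(kin_names):
        lo = i * config.substrates_per_kinase
        hi = lo + config.substrates_per_kinase
        if hi > config.n_phosphosites:
            break
        substrates[kin] = {site_ids[j] for j in site_perm[lo:hi]}
    active = kin_names[:config.n_active_kinases]
    for kin in active:
        idx = [site_ids.index(s) for s in substrates[kin]]
        phospho_vals[np.ix_(idx, np.arange(n))] += config.kinase_substrate_shift
    active_s = pd.Series(config.kinase_substrate_shift, index=active,
                         name="substrate_shift")

    ph_mask = _intensity_missing_mask(phospho_vals,
                                      config.missing_rate_phospho, ph_rng)
    phospho_vals = phospho_vals.copy()
    phospho_vals[ph_mask] = np.nan
    phospho = OmicsMatrix(pd.DataFrame(phospho_vals, index=site_ids,
                                       columns=tumor_ids + nat_ids),
                          layer="phospho", scale="log2")
    ks_map = KinaseSubstrateMap(substrates)

    # --- cell-score layer (immune clusters) ---------------------------------
    cs_rng = streams["cellscore"]
    centers = cs_rng.normal(0.0, 1.0,
                            size=(config.n_celltypes, config.n_immune_clusters))
    cell_vals = centers[:, immune_cluster - 1] + cs_rng.normal(
        0, config.immune_cluster_sd, (config.n_celltypes, n))
    celltypes = [f"CELL{i + 1:03d}" for i in range(config.n_celltypes)]
    cellscore = OmicsMatrix(pd.DataFrame(cell_vals, index=celltypes,
                                         columns=tumor_ids),
                            layer="cellscore", scale="zscore")

    # --- mutations -----------------------------------------------------------
    mut_rng = streams["mutation"]
    counts, W, E = simulate_catalog(n, config.k_signatures,
                                    config.n_mut_per_sample, mut_rng,
                                    sparsity=config.signature_sparsity)
    records = _catalog_to_mutation_records(counts, tumor_ids, genes, mut_rng)
    cols = MutationTable.COLUMNS
    mut_df = (pd.DataFrame(records, columns=cols) if records
              else pd.DataFrame(columns=cols))
    mutations = MutationTable(mut_df)
    exposures = pd.DataFrame(E, index=tumor_ids,
                             columns=[f"SIG{i + 1}" for i in range(config.k_signatures)])
    signatures = pd.DataFrame(W, index=list(CHANNELS_96),
                              columns=exposures.columns)

    # --- survival ------------------------------------------------------------
    surv_rng = streams["survival"]
    lp = np.array([config.subtype_loghr[s - 1] for s in subtype], dtype=float)
    if config.n_biomarkers:
        lp = lp + config.biomarker_loghr * aggressiveness
    lp_s = pd.Series(lp, index=tumor_ids, name="linear_predictor")
    os_time, os_event = simulate_survival(lp, config.baseline_rate,
                                          config.censor_rate, surv_rng)
    dfs_time, dfs_event = simulate_survival(lp + 0.2, config.baseline_rate,
                                            config.censor_rate, surv_rng)

    # --- clinical table -------------------------------------------------------
    cl_rng = streams["clinical"]
    age = cl_rng.integers(35, 85, size=n)
    sex = cl_rng.choice(["M", "F"], size=n, p=[0.58, 0.42])
    stage = cl_rng.choice(["IA", "IB", "IIA", "IIB", "III"], size=n,
                          p=[0.12, 0.34, 0.07, 0.39, 0.08])
    location = cl_rng.choice(["head", "body_tail"], size=n, p=[0.63, 0.37])
    diabetes = cl_rng.choice(["yes", "no", "unknown"], size=n,
                             p=[0.19, 0.80, 0.01])
    metastasis = cl_rng.choice(["yes", "no", "unknown"], size=n,
                               p=[0.40, 0.30, 0.30])
    glucose = np.round(cl_rng.normal(5.6, 1.2, size=n), 2)
    glucose[diabetes == "yes"] += 2.0
    purity = np.round(cl_rng.uniform(0.1, 0.8, size=n), 2)

    def rows(tissue, ids):
        return pd.DataFrame({
            "sample_id": ids, "patient_id": patients, "tissue": tissue,
            "age": age, "sex": sex, "tnm_stage": stage, "location": location,
            "diabetes": diabetes, "metastasis": metastasis,
            "blood_glucose": glucose, "purity": purity,
            "os_time": np.round(os_time, 1), "os_event": os_event,
            "dfs_time": np.round(dfs_time, 1), "dfs_event": dfs_event,
        })

    clinical = ClinicalTable(pd.concat([rows("tumor", tumor_ids),
                                        rows("nat", nat_ids)],
                                       ignore_index=True))

    gene_sets = GeneSetCollection(
        dict(programs), {k: "planted subtype program" for k in programs})

    truth = CohortTruth(
        log2fc=log2fc_s, cis_genes=cis_s, subtype=subtype_s,
        immune_cluster=immune_s, exposures=exposures, signatures=signatures,
        linear_predictor=lp_s, active_kinases=active_s, programs=programs,
        subtype_markers=subtype_markers, biomarkers=biomarkers,
    )
    layers = {"mrna": mrna, "protein": protein, "phospho": phospho,
              "cna": cna_m, "cellscore": cellscore}
    return Cohort(clinical=clinical, layers=layers, mutations=mutations,
                  gene_sets=gene_sets, ks_map=ks_map, truth=truth)
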