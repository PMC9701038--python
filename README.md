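# pgkit

Integrative proteogenomic analysis of paired tumor / non-tumor-adjacent
(NAT) multi-omics cohorts, of the kind assembled for pancreatic ductal
adenocarcinoma (PDAC): whole-exome mutation tables, gene-level copy-number
values, and mRNA / protein / phosphosite abundance matrices for the same
patients, with clinical follow-up.

`pgkit` implements the statistical stages such a study chains together,
each as a tested library function with a thin CLI on top:

- **Mutational signatures** — 96-channel trinucleotide catalogs,
  multiplicative-update NMF (V ≈ WH, Frobenius objective, best of
  restarts), a noise-calibrated elbow for the number of signatures, and
  cosine matching of extracted signatures to a reference catalog.
- **Copy-number cis/trans effects** — Spearman screens of CNA values
  against same-gene (*cis*) or other-gene (*trans*) expression, and
  Fisher-exact tests for event co-occurrence / mutual exclusivity.
- **Differential expression** — Welch t / Wilcoxon / ANOVA / Kruskal
  with Benjamini–Hochberg control and dual fold-change + q thresholds,
  plus the biomarker filter cascades (complete-quantification →
  differential → hazardous; subtype-marker one-vs-rest screen).
- **Single-sample enrichment** — a GSVA-style weighted KS random walk
  over per-sample gene rankings, serving pathway scores, TF activity over
  regulons, and the multi-gene proliferation score (MGPS).
- **KSEA** — kinase activity z = (mean(substrates) − mean(all sites)) ·
  √m / sd(all sites) from phosphosite fold changes.
- **Consensus subtyping** — subsampled hierarchical clustering on
  1 − Spearman distances, consensus matrices with CDF / delta-area /
  silhouette diagnostics, and cluster merging (e.g. five immune clusters
  → three).
- **Survival** — Kaplan–Meier, log-rank, maximally-selected-rank-statistic
  cutpoints with selection-adjusted permutation p-values, and univariate
  Cox (Efron ties).
- **Synthetic cohorts** — a generator that plants tumor/NAT effects, cis
  genes, signature mixtures, subtypes, immune clusters, active kinases
  and survival structure, and records everything in a truth ledger so
  every stage is testable without any external download.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

Generate a synthetic cohort, extract mutational signatures, and recover
the planted proteomic subtypes:

```python
import numpy as np
from pgkit import (CohortConfig, generate_cohort, build_catalog, select_k,
                   factorize, match_to_reference)
from pgkit.subtyping import select_features, consensus_cluster, choose_k
from pgkit.io import OmicsMatrix
from sklearn.metrics import adjusted_rand_score

cfg = CohortConfig(n_patients=100, n_genes=600, n_phosphosites=300,
                   program_size=80, n_cis_genes=40, n_mut_per_sample=60,
                   rng_seed=7)
cohort = generate_cohort(cfg)
tumors = [s for s in cohort.layers["protein"].values.columns
          if s.endswith("_T")]

catalog = build_catalog(cohort.mutations, tumors)
k = select_k(catalog, range(1, 6), rng_seed=7)
dec = factorize(catalog, k, rng_seed=7, n_restarts=3, max_iter=1000)
print(f"signatures: K={k}")
print(match_to_reference(dec.W, cohort.truth.signatures).to_string(index=False))

tum = cohort.layers["protein"].subset_samples(tumors)
feats = select_features(tum, 0.5)
res = consensus_cluster(OmicsMatrix(tum.values.loc[feats], "protein", "log2"),
                        range(2, 6), n_reps=300, rng_seed=7)
kk = choose_k(res)
ari = adjusted_rand_score(cohort.truth.subtype.loc[res.assignments[kk].index],
                          res.assignments[kk])
print(f"subtypes: k={kk}, ARI vs planted truth = {ari:.2f}, "
      f"silhouette = {res.silhouette[kk]:.2f}")
```

Output:

```
signatures: K=3
signature reference   cosine
       S1      SIG1 0.990386
       S2      SIG3 0.992641
       S3      SIG2 0.994445
subtypes: k=3, ARI vs planted truth = 1.00, silhouette = 1.00
```

The cohort was generated with three mutational signatures and three
proteomic subtypes; the K selector finds both threes, each extracted
signature matches its planted counterpart at cosine ≥ 0.99, and the
consensus assignment reproduces the planted subtype labels exactly
(adjusted Rand index 1.0) with a fully crisp consensus matrix
(silhouette 1.0).

The same stages are available from the shell:

```sh
pgkit simulate --out cohort/ --seed 7
pgkit signatures --maf cohort/mutations.maf.tsv --clinical cohort/clinical.tsv --seed 7
pgkit subtype --matrix cohort/protein.tsv --k-range 2,3,4,5 --seed 7
pgkit run-all --out results/ --seed 7
```

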