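"""Readers/writers and shared ID conventions for the pipeline's formats.

All molecular layers travel as :class:`OmicsMatrix` (features x samples,
missing allowed for MS-based layers), variants as :class:`MutationTable`,
gene sets as :class:`GeneSetCollection` and kinase->substrate relations as
:class:`KinaseSubstrateMap`.  On disk everything is plain TSV/GMT; missing
values are empty cells or ``NA`` and are kept distinct from zero (an
unquantified protein is not an absent protein).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

LAYERS = ("mrna", "protein", "phospho", "cna", "cellscore")
SCALES = ("linear_nonneg", "log2", "zscore", "logratio")

VARIANT_CLASSES = ("missense", "nonsense", "inframe", "frameshift", "other")

#: MAF Variant_Classification -> internal 5-level class
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "In_Frame_Del": "inframe",
    "In_Frame_Ins": "inframe",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Phosphosite ID grammar: GENE_p<residue><position>, residue in S/T/Y.
SITE_ID_RE = re.compile(r"^([A-Za-z0-9.-]+)_p([STY])(\d+)$")

#: Canonical 96-channel trinucleotide ordering: six pyrimidine-centred
#: substitutions x 16 flanking contexts, both alphabetical.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


class OmicsIOError(ValueError):
    """Raised on malformed or inconsistent input files."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_context(context: str, ref: str, alt: str) -> tuple[str, str, str]:
    """Normalize an SNV to the pyrimidine-centred strand.

    Returns ``(context, ref, alt)`` with the centre base in {C, T};
    purine-centred records are reverse-complemented.  Normalizing an
    already-normalized record is a no-op.
    """
    context = context.upper()
    ref, alt = ref.upper(), alt.upper()
    if len(context) != 3 or any(b not in "ACGT" for b in context):
        raise OmicsIOError(f"invalid trinucleotide context {context!r}")
    if ref not in "ACGT" or alt not in "ACGT":
        raise OmicsIOError(f"invalid SNV alleles {ref!r}>{alt!r}")
    if context[1] != ref:
        raise OmicsIOError(
            f"context centre {context[1]!r} does not match ref allele {ref!r}"
        )
    if ref in "AG":
        return revcomp(context), revcomp(ref), revcomp(alt)
    return context, ref, alt


def channel_of(context: str, ref: str, alt: str) -> str:
    """96-channel label for a (pyrimidine-normalized) SNV."""
    context, ref, alt = normalize_context(context, ref, alt)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def parse_site_id(site_id: str) -> tuple[str, str, int]:
    """Split ``GENE_pS807`` into ``("GENE", "S", 807)``."""
    m = SITE_ID_RE.match(site_id)
    if m is None:
        raise OmicsIOError(
            f"malformed phosphosite ID {site_id!r}; expected GENE_p[STY]<pos>"
        )
    return m.group(1), m.group(2), int(m.group(3))


def gene_of_feature(feature_id: str) -> str:
    """Gene symbol behind a feature ID (phosphosites map via their prefix)."""
    if "_p" in feature_id:
        try:
            return parse_site_id(feature_id)[0]
        except OmicsIOError:
            pass
    return feature_id


# ---------------------------------------------------------------------------
# OmicsMatrix
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """One molecular layer: features x samples with optional missingness."""

    values: pd.DataFrame
    layer: str
    scale: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise OmicsIOError(f"unknown layer {self.layer!r}")
        if self.scale not in SCALES:
            raise OmicsIOError(f"unknown scale {self.scale!r}")
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise OmicsIOError(f"duplicate feature IDs: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise OmicsIOError(f"duplicate sample IDs: {dupes}")
        if self.layer == "cna" and self.scale != "logratio":
            raise OmicsIOError("cna layer requires logratio scale")
        if self.layer in ("mrna", "protein") and self.scale == "linear_nonneg":
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise OmicsIOError(
                    f"{self.layer} on linear_nonneg scale has negative values"
                )
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values[list(sample_ids)], self.layer, self.scale)

    def to_linear(self) -> pd.DataFrame:
        """Values on linear scale (2**x for log2 data)."""
        if self.scale == "log2":
            return 2.0 ** self.values
        return self.values


def read_matrix(path, layer: str, scale: str) -> OmicsMatrix:
    """Read a features x samples TSV (first column = feature IDs).

    Empty cells and ``NA`` become missing.  Non-numeric cells and duplicate
    feature IDs are rejected with the offending row/column named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, comment="#")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise OmicsIOError(f"duplicate feature IDs in {path}: {dupes}")
    parsed = {}
    for col in df.columns:
        cells = df[col].where(~df[col].isin(["", "NA", "nan"]))
        try:
            parsed[col] = pd.to_numeric(cells)
        except (ValueError, TypeError):
            bad = cells[pd.to_numeric(cells, errors="coerce").isna() & cells.notna()]
            row = bad.index[0] if len(bad) else "?"
            raise OmicsIOError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            ) from None
    out = pd.DataFrame(parsed, index=df.index)
    return OmicsMatrix(out, layer=layer, scale=scale)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id",
                         float_format="%.12g")


# ---------------------------------------------------------------------------
# ClinicalTable
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "sample_id", "patient_id", "tissue", "age", "sex", "tnm_stage",
    "location", "diabetes", "metastasis", "blood_glucose", "purity",
    "os_time", "os_event", "dfs_time", "dfs_event",
]


@dataclass
class ClinicalTable:
    """Per-sample clinical records; tumors pair with NATs via patient_id."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise OmicsIOError(f"clinical table missing columns: {missing}")
        rec = self.records
        if rec["sample_id"].duplicated().any():
            raise OmicsIOError("duplicate sample IDs in clinical table")
        if not rec["tissue"].isin(["tumor", "nat"]).all():
            raise OmicsIOError("tissue must be 'tumor' or 'nat'")
        for tis in ("tumor", "nat"):
            sub = rec[rec["tissue"] == tis]
            if sub["patient_id"].duplicated().any():
                raise OmicsIOError(f"patient with more than one {tis} sample")
        for col in ("os_time", "dfs_time"):
            times = pd.to_numeric(rec[col], errors="coerce")
            if (times.dropna() < 0).any():
                raise OmicsIOError(f"negative {col}")
        for col in ("os_event", "dfs_event"):
            ev = pd.to_numeric(rec[col], errors="coerce").dropna()
            if not ev.isin([0, 1]).all():
                raise OmicsIOError(f"{col} must be 0/1")
        self.records = rec.reset_index(drop=True)

    def tumors(self) -> pd.DataFrame:
        return self.records[self.records["tissue"] == "tumor"]

    def nats(self) -> pd.DataFrame:
        return self.records[self.records["tissue"] == "nat"]

    def tissue_of(self) -> pd.Series:
        return self.records.set_index("sample_id")["tissue"]


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str},
                     comment="#")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# MutationTable
# ---------------------------------------------------------------------------

MAF_REQUIRED = [
    "Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification",
    "Reference_Allele", "Tumor_Seq_Allele2", "Trinucleotide_Context",
]


@dataclass
class MutationTable:
    """Per-variant records with pyrimidine-normalized SNV contexts."""

    records: pd.DataFrame

    COLUMNS = ["sample_id", "gene", "variant_class", "ref_allele",
               "alt_allele", "trinucleotide_context", "protein_change"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise OmicsIOError(f"mutation table missing columns: {missing}")
        bad = ~self.records["variant_class"].isin(VARIANT_CLASSES)
        if bad.any():
            raise OmicsIOError(
                f"unknown variant classes: {sorted(self.records.loc[bad, 'variant_class'].unique())}"
            )
        ctx = self.records["trinucleotide_context"].dropna()
        centred = ctx.str.len().eq(3) & ctx.str[1].isin(list("CT"))
        if not centred.all():
            raise OmicsIOError("non-normalized trinucleotide contexts present")
        self.records = self.records.reset_index(drop=True)

    def snvs(self) -> pd.DataFrame:
        """Qualifying single-nucleotide variants with a context."""
        rec = self.records
        is_snv = (
            rec["ref_allele"].isin(list("ACGT"))
            & rec["alt_allele"].isin(list("ACGT"))
            & rec["trinucleotide_context"].notna()
        )
        return rec[is_snv]

    def __len__(self) -> int:
        return len(self.records)


def read_maf(path) -> MutationTable:
    """Read a MAF-like TSV (subset of columns), normalizing SNV contexts."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise OmicsIOError(f"MAF missing required columns: {missing}")
    rows = []
    for _, r in df.iterrows():
        ref, alt = r["Reference_Allele"], r["Tumor_Seq_Allele2"]
        ctx = r["Trinucleotide_Context"] or None
        vclass = MAF_CLASS_MAP.get(r["Variant_Classification"], "other")
        is_snv = len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT"
        if is_snv and ctx:
            ctx, ref, alt = normalize_context(ctx, ref, alt)
        else:
            ctx = None
        rows.append({
            "sample_id": r["Tumor_Sample_Barcode"],
            "gene": r["Hugo_Symbol"],
            "variant_class": vclass,
            "ref_allele": ref,
            "alt_allele": alt,
            "trinucleotide_context": ctx,
            "protein_change": r.get("Protein_Change") or None,
        })
    cols = MutationTable.COLUMNS
    rec = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    return MutationTable(rec)


def write_maf(table: MutationTable, path) -> None:
    df = pd.DataFrame({
        "Hugo_Symbol": table.records["gene"],
        "Tumor_Sample_Barcode": table.records["sample_id"],
        "Variant_Classification": table.records["variant_class"].map({
            "missense": "Missense_Mutation", "nonsense": "Nonsense_Mutation",
            "inframe": "In_Frame_Del", "frameshift": "Frame_Shift_Del",
            "other": "Silent",
        }),
        "Reference_Allele": table.records["ref_allele"],
        "Tumor_Seq_Allele2": table.records["alt_allele"],
        "Trinucleotide_Context": table.records["trinucleotide_context"],
        "Protein_Change": table.records["protein_change"],
    })
    df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# GeneSetCollection / KinaseSubstrateMap
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named, non-empty feature sets (pathways, TF regulons, programs)."""

    sets: dict[str, set[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise OmicsIOError(f"gene set {name!r} has zero members")
        self.sets = {n: set(m) for n, m in self.sets.items()}

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    prov: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise OmicsIOError(
                    f"GMT line {lineno}: set {parts[0]!r} has zero members"
                )
            name, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
            if not members:
                raise OmicsIOError(f"GMT line {lineno}: set {name!r} has zero members")
            if name in sets:
                raise OmicsIOError(f"duplicate set name {name!r}")
            sets[name] = set(members)
            prov[name] = desc
    return GeneSetCollection(sets, prov)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.provenance.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


@dataclass
class KinaseSubstrateMap:
    """kinase -> set of phosphosite IDs (GENE_p[STY]<pos>)."""

    substrates: dict[str, set[str]]

    def __post_init__(self) -> None:
        for kinase, sites in self.substrates.items():
            for site in sites:
                parse_site_id(site)  # raises on malformed IDs
        self.substrates = {k: set(v) for k, v in self.substrates.items()}

    def kinases(self) -> list[str]:
        return list(self.substrates)

    def __getitem__(self, kinase: str) -> set[str]:
        return self.substrates[kinase]


def read_ks_map(path) -> KinaseSubstrateMap:
    """Two-column TSV: kinase<TAB>phosphosite_id (header optional)."""
    substrates: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OmicsIOError(f"ks-map line {lineno}: expected 2 columns")
            kinase, site = parts
            if lineno == 1 and kinase.lower() in ("kinase", "kinase_id"):
                continue
            parse_site_id(site)
            substrates.setdefault(kinase, set()).add(site)
    return KinaseSubstrateMap(substrates)


def write_ks_map(ks_map: KinaseSubstrateMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("kinase\tsite\n")
        for kinase in ks_map.kinases():
            for site in sorted(ks_map.substrates[kinase]):
                fh.write(f"{kinase}\t{site}\n")
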