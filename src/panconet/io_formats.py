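"""Readers, writers and validated containers for every table the pipeline touches.

All on-disk formats are UTF-8 tab-separated text with mandatory headers:
expression/β/CNA matrices (first column gene ids, remaining columns samples),
SEG-like segment files, GMT gene-set collections, BED-like gene models,
clinical tables and two-column edge lists.

Conventions
-----------
* Missing values in tables are encoded by the literal strings ``"NA"`` and
  ``""`` (configurable via the ``na_values`` argument of each reader).
* All genomic intervals are held 1-based inclusive internally (SEG
  convention); BED-like gene-model input is converted on read.
* Chromosome labels are normalised to a bare style without the ``chr``
  prefix.
* TCGA-like sample barcodes are truncated to the patient field by joining
  the first ``n_fields`` ``-``-separated fields; non-barcode ids need an
  explicit sample table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "GeneModel",
    "ProbeAnnotation",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "read_segments",
    "write_segments",
    "read_gene_model",
    "read_probe_annotation",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "read_mutations",
    "read_edge_list",
    "write_edge_list",
    "canonical_pair",
    "normalize_chromosome",
    "patient_from_barcode",
    "PROMOTER_TAGS",
]

NA_VALUES = ("NA", "")

#: 450K region annotations counted as promoter: 1500 bp upstream of the TSS
#: through the first exon.
PROMOTER_TAGS = frozenset({"TSS1500", "TSS200", "5'UTR", "first_exon"})

VALID_UNITS = ("counts", "cpm", "logcpm", "beta", "cna")


def normalize_chromosome(label: str) -> str:
    """Strip an optional ``chr`` prefix so mixed sources agree on one style."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def patient_from_barcode(sample_id: str, delimiter: str = "-", n_fields: int = 3) -> str:
    """Truncate a TCGA-like barcode to its patient field.

    ``TCGA-A1-A0SB-01A`` -> ``TCGA-A1-A0SB`` with the defaults.  Ids with
    fewer fields are returned unchanged.
    """
    parts = str(sample_id).split(delimiter)
    return delimiter.join(parts[:n_fields]) if len(parts) > n_fields else str(sample_id)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered gene pair lexicographically. Idempotent; rejects self-loops."""
    if a == b:
        raise ValueError(f"self-loop on {a!r} is not a valid edge")
    return (a, b) if a < b else (b, a)


@dataclass
class ExpressionMatrix:
    """A dense genes × samples grid with a unit tag.

    ``values`` is a pandas DataFrame indexed by gene id with sample-id
    columns. ``unit`` is one of ``counts``, ``cpm``, ``logcpm``, ``beta``
    (methylation fraction) or ``cna`` (copy-number log ratio). Counts must
    be non-negative and β values must lie in [0, 1]; NaN marks missingness
    for β/CNA matrices.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.unit == "counts":
            if np.isnan(arr).any():
                raise ValueError("count matrix may not contain missing values")
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
        if self.unit == "beta":
            finite = arr[~np.isnan(arr)]
            if finite.size and ((finite < 0).any() or (finite > 1).any()):
                raise ValueError("beta values must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.unit)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = [s for s in samples if s in self.values.columns]
        return ExpressionMatrix(self.values[samples], self.unit)


@dataclass
class SampleTable:
    """Sample-level metadata: patient id, cancer type and tumor/normal status."""

    table: pd.DataFrame  # columns: sample_id, patient_id, cancer_type, tissue_status

    REQUIRED = ("sample_id", "patient_id", "cancer_type", "tissue_status")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample table missing columns {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample table")
        bad = set(self.table["tissue_status"]) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"tissue_status must be 'tumor' or 'normal', got {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    def samples(self, cancer_type: str | None = None, tissue_status: str | None = None) -> list[str]:
        t = self.table
        if cancer_type is not None:
            t = t[t["cancer_type"] == cancer_type]
        if tissue_status is not None:
            t = t[t["tissue_status"] == tissue_status]
        return list(t["sample_id"])

    def patient_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["patient_id"]))

    def cancer_types(self) -> list[str]:
        return sorted(self.table["cancer_type"].unique())


@dataclass
class GeneModel:
    """Gene coordinates (1-based inclusive) with strand, TSS and first-exon end."""

    table: pd.DataFrame  # gene_id, chromosome, strand, tss, first_exon_end, gene_start, gene_end

    def __post_init__(self) -> None:
        t = self.table
        required = ["gene_id", "chromosome", "strand", "tss", "first_exon_end", "gene_start", "gene_end"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"gene model missing columns {missing}")
        if (t["gene_start"] > t["gene_end"]).any():
            raise ValueError("gene_start must be <= gene_end")
        if (t[["tss", "first_exon_end", "gene_start", "gene_end"]] <= 0).any().any():
            raise ValueError("gene coordinates must be positive (1-based)")
        bad = set(t["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"strand must be '+' or '-', got {sorted(bad)}")
        t["chromosome"] = t["chromosome"].map(normalize_chromosome)


@dataclass
class ProbeAnnotation:
    """450K probe → gene assignments with region tags (TSS1500/TSS200/... )."""

    table: pd.DataFrame  # probe_id, gene_id, region_tags (frozenset per row)

    def __post_init__(self) -> None:
        t = self.table
        for c in ("probe_id", "gene_id", "region_tags"):
            if c not in t.columns:
                raise ValueError(f"probe annotation missing column {c!r}")
        if t.duplicated(subset=["probe_id", "gene_id"]).any():
            raise ValueError("duplicate (probe, gene) annotation rows")
        if any(len(tags) == 0 for tags in t["region_tags"]):
            raise ValueError("region_tags must be non-empty")


class GeneSetCollection(dict):
    """Mapping of set id -> (description, ordered member gene ids).

    Member lists are deduplicated preserving first-occurrence order and must
    be non-empty.
    """

    def __init__(self, sets: Mapping[str, tuple[str, Sequence[str]]] | None = None):
        super().__init__()
        for set_id, (desc, members) in (sets or {}).items():
            self.add(set_id, desc, members)

    def add(self, set_id: str, description: str, members: Sequence[str]) -> None:
        deduped = list(dict.fromkeys(members))
        if not deduped:
            raise ValueError(f"gene set {set_id!r} has no members")
        self[set_id] = (description, deduped)

    def members(self, set_id: str) -> list[str]:
        return list(self[set_id][1])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, na_values=NA_VALUES, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=list(na_values), keep_default_na=False, **kw)


def read_expression_matrix(path, unit: str, na_values=NA_VALUES) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column gene ids, header of sample ids).

    Non-numeric cells raise a parse error naming the offending row and
    column; duplicated gene or sample ids raise a validation error.
    """
    df = _read_tsv(path, na_values=na_values, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-numeric value in column {col!r}, row {gene!r}")
        out[col] = converted
    out.index.name = "gene_id"
    return ExpressionMatrix(out, unit)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_sample_table(path, na_values=NA_VALUES) -> SampleTable:
    return SampleTable(_read_tsv(path, na_values=na_values, dtype=str))


def read_segments(path, na_values=NA_VALUES) -> pd.DataFrame:
    """Read a SEG-like file into a table sorted by (sample, chromosome, start).

    Expected columns: ``sample``, ``chrom``, ``start``, ``end``, ``seg_mean``
    (1-based inclusive coordinates). Overlapping segments are retained; the
    containment rule downstream resolves ambiguity as missingness.
    """
    df = _read_tsv(path, na_values=na_values)
    rename = {"sample": "sample_id", "chrom": "chromosome", "seg.mean": "seg_mean"}
    df = df.rename(columns={c: rename.get(c.lower(), c.lower()) for c in df.columns})
    required = ["sample_id", "chromosome", "start", "end", "seg_mean"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"segment file missing columns {missing}")
    df = df[required].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["seg_mean"] = df["seg_mean"].astype(float)
    if (df["start"] > df["end"]).any():
        row = df[df["start"] > df["end"]].iloc[0]
        raise ValueError(f"segment start > end for sample {row['sample_id']} at {row['chromosome']}:{row['start']}")
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    return df.sort_values(["sample_id", "chromosome", "start"], kind="mergesort").reset_index(drop=True)


def write_segments(segments: pd.DataFrame, path) -> None:
    out = segments.rename(columns={"sample_id": "sample", "chromosome": "chrom"})
    out.to_csv(path, sep="\t", index=False)


def read_gene_model(path, zero_based: bool = True, na_values=NA_VALUES) -> GeneModel:
    """Read a BED-like gene model.

    Expected columns: chrom, start, end, gene_id, strand, tss,
    first_exon_end.  With ``zero_based`` (BED convention) start positions
    are converted to the internal 1-based inclusive convention.
    """
    df = _read_tsv(path, na_values=na_values)
    df = df.rename(columns={c: c.lower() for c in df.columns})
    rename = {"chrom": "chromosome", "start": "gene_start", "end": "gene_end"}
    df = df.rename(columns=rename)
    for col in ("gene_start", "gene_end", "tss", "first_exon_end"):
        df[col] = df[col].astype(int)
    if zero_based:
        df["gene_start"] = df["gene_start"] + 1  # half-open 0-based -> 1-based inclusive
        df["tss"] = df["tss"] + 1
    return GeneModel(df)


def read_probe_annotation(path, na_values=NA_VALUES) -> ProbeAnnotation:
    """Read probe annotation with a ``region_tags`` column of ``;``-separated tags."""
    df = _read_tsv(path, na_values=na_values, dtype=str)
    df["region_tags"] = df["region_tags"].map(
        lambda s: frozenset(t.strip() for t in str(s).split(";") if t.strip())
    )
    return ProbeAnnotation(df)


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file (set id, description, tab-separated members)."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            set_id, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            coll.add(set_id, desc, members)
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, (desc, members) in collection.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


_TNM_COLUMNS = ("ajcc_t", "ajcc_n", "ajcc_m", "t_stage", "n_stage", "m_stage")


def merge_tnm_substage(value):
    """Collapse AJCC TNM substages by stripping trailing letter modifiers.

    ``N1a``/``N1b`` -> ``N1``, ``T2b`` -> ``T2``; values without a trailing
    letter pass through unchanged.
    """
    if not isinstance(value, str):
        return value
    v = value.strip()
    if len(v) >= 3 and v[-1].isalpha() and v[-2].isdigit():
        return v[:-1]
    return v


def read_clinical(
    path,
    na_values=NA_VALUES,
    missing_frac: float = 0.5,
    tnm_columns: Sequence[str] = _TNM_COLUMNS,
) -> pd.DataFrame:
    """Read and clean a clinical table.

    * Columns with more than ``missing_frac`` missing values are dropped
      (``patient_id`` and the survival source columns are always kept).
    * TNM stage columns are merged by stripping trailing substage letters.
    * ``survival_time`` is ``death_days_to`` for deceased patients and
      ``last_contact_days_to`` otherwise; ``survival_event`` is True when
      vital status is ``dead`` (case-insensitive).
    """
    df = _read_tsv(path, na_values=na_values, dtype=str)
    df = df.rename(columns={c: c.lower() for c in df.columns})
    if "patient_id" not in df.columns:
        raise ValueError("clinical table must have a patient_id column")
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient ids in clinical table")

    protected = {"patient_id", "death_days_to", "last_contact_days_to", "vital_status"}
    n = len(df)
    keep = [
        c for c in df.columns
        if c in protected or (n > 0 and df[c].isna().sum() / n <= missing_frac)
    ]
    df = df[keep]

    for col in tnm_columns:
        if col in df.columns:
            df[col] = df[col].map(merge_tnm_substage)

    if "vital_status" in df.columns:
        dead = df["vital_status"].str.lower().fillna("") == "dead"
        death = pd.to_numeric(df.get("death_days_to"), errors="coerce")
        contact = pd.to_numeric(df.get("last_contact_days_to"), errors="coerce")
        df["survival_event"] = dead
        df["survival_time"] = np.where(dead, death, contact)
        bad = df["survival_time"] < 0
        if bad.any():
            raise ValueError("negative survival times")
    return df.reset_index(drop=True)


def read_mutations(
    maf_like_path,
    q_table_path,
    q_threshold: float = 0.1,
    patients: Sequence[str] | None = None,
    na_values=NA_VALUES,
) -> pd.DataFrame:
    """Build the per-patient binary mutation table.

    The MAF-like file has columns ``patient_id``, ``gene_id`` (extra columns
    such as variant class are ignored: all variant types are combined).
    Multiple variant rows of one patient collapse to a single ``mutant``
    status. The q table (``gene_id``, ``q_value``) filters genes to those
    called significantly mutated upstream (q < ``q_threshold``). Patients
    listed (or seen in the MAF) without a variant in a retained gene are
    ``wild_type`` for it.

    Returns a DataFrame with columns patient_id, gene_id, status, q_value.
    """
    qt = _read_tsv(q_table_path, na_values=na_values)
    qt = qt.rename(columns={c: c.lower() for c in qt.columns})
    qt["q_value"] = qt["q_value"].astype(float)
    if ((qt["q_value"] < 0) | (qt["q_value"] > 1)).any():
        raise ValueError("q values must lie in [0, 1]")
    kept = qt[qt["q_value"] < q_threshold]
    genes = list(kept["gene_id"])
    qmap = dict(zip(kept["gene_id"], kept["q_value"]))

    maf = _read_tsv(maf_like_path, na_values=na_values, dtype=str)
    maf = maf.rename(columns={c: c.lower() for c in maf.columns})
    mutated = set(zip(maf["patient_id"], maf["gene_id"]))

    all_patients = list(patients) if patients is not None else sorted(maf["patient_id"].unique())
    rows = [
        (p, g, "mutant" if (p, g) in mutated else "wild_type", qmap[g])
        for p in all_patients
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["patient_id", "gene_id", "status", "q_value"])


def read_edge_list(path, na_values=NA_VALUES) -> pd.DataFrame:
    """Read an edge list TSV (gene_a, gene_b, optional sign and weight).

    Pairs are canonicalised (gene_a < gene_b); self-loops raise; a pair
    appearing twice raises.
    """
    df = _read_tsv(path, na_values=na_values, dtype=str)
    df = df.rename(columns={c: c.lower() for c in df.columns})
    if "gene_a" not in df.columns or "gene_b" not in df.columns:
        raise ValueError("edge list must have gene_a and gene_b columns")
    pairs = [canonical_pair(a, b) for a, b in zip(df["gene_a"], df["gene_b"])]
    df["gene_a"] = [p[0] for p in pairs]
    df["gene_b"] = [p[1] for p in pairs]
    if df.duplicated(subset=["gene_a", "gene_b"]).any():
        raise ValueError("unordered pair appears more than once in edge list")
    if "weight" in df.columns:
        df["weight"] = df["weight"].astype(float)
    if "sign" in df.columns:
        bad = set(df["sign"].dropna()) - {"+", "-"}
        if bad:
            raise ValueError(f"edge sign must be '+' or '-', got {sorted(bad)}")
    return df.reset_index(drop=True)


def write_edge_list(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
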