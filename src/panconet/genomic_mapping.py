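"""Segment→gene copy-number mapping, promoter methylation summarisation,
missingness filtering and k-nearest-neighbor imputation.

Copy-number segments are assigned to a gene only when the gene's full span
is contained in exactly one segment of that sample; straddled, uncovered or
ambiguously covered genes are missing. Genes missing in more than half of
samples are dropped, the rest imputed from the 10 nearest gene rows.
Patient-level somatic values are tumor minus the averaged normals; patients
with more than one tumor sample or no normal are excluded. Promoter
methylation per gene is the mean β of probes tagged TSS1500, TSS200, 5'UTR
or first exon.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    ProbeAnnotation,
    PROMOTER_TAGS,
    SampleTable,
)

__all__ = [
    "map_segments_to_genes",
    "drop_high_missing",
    "knn_impute",
    "tumor_minus_normal",
    "map_probes_to_promoters",
    "promoter_tags_from_gene_model",
]


def map_segments_to_genes(segments: pd.DataFrame, gene_model: GeneModel) -> ExpressionMatrix:
    """Per-sample gene-level segment means under the full-containment rule.

    value(g, s) = seg_mean of the unique segment of sample s fully
    containing [gene_start, gene_end] (1-based inclusive on both sides).
    Genes straddling segment boundaries or not covered are missing; a gene
    fully contained in two overlapping segments is missing with a warning.
    """
    genes = gene_model.table
    samples = sorted(segments["sample_id"].unique())
    out = pd.DataFrame(np.nan, index=genes["gene_id"].tolist(), columns=samples)
    ambiguous = 0
    for sample, seg_s in segments.groupby("sample_id"):
        for chrom, seg_c in seg_s.groupby("chromosome"):
            g = genes[genes["chromosome"] == chrom]
            if g.empty:
                continue
            starts = seg_c["start"].to_numpy()
            ends = seg_c["end"].to_numpy()
            means = seg_c["seg_mean"].to_numpy()
            for gid, gs, ge in zip(g["gene_id"], g["gene_start"], g["gene_end"]):
                hit = (starts <= gs) & (ends >= ge)
                n_hit = int(hit.sum())
                if n_hit == 1:
                    out.at[gid, sample] = means[hit][0]
                elif n_hit > 1:
                    ambiguous += 1
    if ambiguous:
        warnings.warn(f"{ambiguous} (gene, sample) pairs covered by overlapping segments; set missing")
    return ExpressionMatrix(out, "cna")


def drop_high_missing(matrix: ExpressionMatrix, frac: float = 0.5) -> ExpressionMatrix:
    """Drop genes missing in strictly more than ``frac`` of samples."""
    vals = matrix.values
    missing_frac = vals.isna().mean(axis=1)
    return ExpressionMatrix(vals.loc[missing_frac <= frac].copy(), matrix.unit)


def knn_impute(matrix: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute missing entries from the k nearest gene rows.

    Distance between two gene rows is the Euclidean distance over columns
    observed in both, rescaled by √(n_columns / n_shared) to compensate for
    varying overlap. For each missing (gene, sample), the imputed value is
    the mean of the k nearest genes that are observed at that sample —
    nearer genes lacking a value there are skipped in favour of the next
    nearest. If no neighbor is observed at the sample, the gene's row mean
    is used with a warning. Observed entries are never altered.
    """
    vals = matrix.values
    x = vals.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_genes < k + 1:
        raise ValueError(f"kNN imputation needs more than k={k} genes")
    obs = ~np.isnan(x)
    if obs.all():
        return ExpressionMatrix(vals.copy(), matrix.unit)

    x0 = np.where(obs, x, 0.0)
    # pairwise squared distances over shared observed columns
    shared = obs.astype(float) @ obs.T.astype(float)
    sq = (x0**2 * obs) @ obs.T.astype(float)
    cross = x0 @ x0.T
    d2 = sq + sq.T - 2 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = d2 * (n_samples / shared)
    d2[shared == 0] = np.inf
    np.fill_diagonal(d2, np.inf)

    out = x.copy()
    fallback = 0
    order_cache: dict[int, np.ndarray] = {}
    for g in range(n_genes):
        miss_cols = np.nonzero(~obs[g])[0]
        if miss_cols.size == 0:
            continue
        order = order_cache.get(g)
        if order is None:
            order = np.argsort(d2[g], kind="stable")
            order_cache[g] = order
        for s in miss_cols:
            candidates = [h for h in order if np.isfinite(d2[g, h]) and obs[h, s]][:k]
            if candidates:
                out[g, s] = x[candidates, s].mean()
            else:
                row = x[g, obs[g]]
                out[g, s] = row.mean() if row.size else np.nan
                fallback += 1
    if fallback:
        warnings.warn(f"{fallback} entries imputed by row mean (no observed neighbor)")
    return ExpressionMatrix(pd.DataFrame(out, index=vals.index, columns=vals.columns), matrix.unit)


def tumor_minus_normal(gene_values: ExpressionMatrix, sample_table: SampleTable) -> ExpressionMatrix:
    """Somatic patient-level values: tumor sample minus averaged normals.

    Patients with more than one tumor sample or without any normal sample
    are excluded (logged via warning). Columns of the result are patient
    ids.
    """
    st = sample_table.table
    st = st[st["sample_id"].isin(gene_values.sample_ids)]
    excluded = []
    cols = {}
    for patient, rows in st.groupby("patient_id"):
        tumors = rows.loc[rows["tissue_status"] == "tumor", "sample_id"].tolist()
        normals = rows.loc[rows["tissue_status"] == "normal", "sample_id"].tolist()
        if len(tumors) != 1 or len(normals) == 0:
            excluded.append(patient)
            continue
        t = gene_values.values[tumors[0]]
        n = gene_values.values[normals].mean(axis=1)
        cols[patient] = t - n
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} patients without exactly one tumor and >=1 normal sample"
        )
    if not cols:
        return ExpressionMatrix(pd.DataFrame(index=gene_values.values.index), "cna")
    return ExpressionMatrix(pd.DataFrame(cols), "cna")


def map_probes_to_promoters(
    beta_matrix: ExpressionMatrix, probe_annotation: ProbeAnnotation
) -> ExpressionMatrix:
    """Gene-level promoter β: mean over promoter-region probes per sample.

    A probe counts toward a gene's promoter when any of its region tags for
    that gene is TSS1500, TSS200, 5'UTR or first exon (body/3'UTR-only
    probes are excluded). Genes with no promoter probe are absent from the
    output; the mean skips missing probe values.
    """
    if beta_matrix.unit != "beta":
        raise ValueError("expected a beta matrix")
    ann = probe_annotation.table
    promoter = ann[ann["region_tags"].map(lambda tags: bool(tags & PROMOTER_TAGS))]
    rows = {}
    for gene, probes in promoter.groupby("gene_id"):
        ids = [p for p in probes["probe_id"] if p in beta_matrix.values.index]
        if ids:
            rows[gene] = beta_matrix.values.loc[ids].mean(axis=0, skipna=True)
    if not rows:
        return ExpressionMatrix(pd.DataFrame(columns=beta_matrix.sample_ids, dtype=float), "beta")
    return ExpressionMatrix(pd.DataFrame(rows).T, "beta")


def promoter_tags_from_gene_model(
    probe_positions: pd.DataFrame, gene_model: GeneModel, upstream: int = 1500
) -> ProbeAnnotation:
    """Derive promoter/body region tags from probe coordinates.

    Fallback for annotation files lacking region tags. The promoter of a
    gene runs from ``upstream`` bp upstream of the TSS (strand-aware)
    through the end of the first exon; probes inside it are tagged TSS1500,
    all other probes within the gene span are tagged body.
    ``probe_positions`` needs columns probe_id, chromosome, position.
    """
    rows = []
    gm = gene_model.table
    for _, probe in probe_positions.iterrows():
        chrom, posn = probe["chromosome"], int(probe["position"])
        for _, g in gm[gm["chromosome"] == chrom].iterrows():
            if g["strand"] == "+":
                prom_lo, prom_hi = g["tss"] - upstream, g["first_exon_end"]
            else:
                prom_lo, prom_hi = g["first_exon_end"], g["tss"] + upstream
            if prom_lo <= posn <= prom_hi:
                rows.append((probe["probe_id"], g["gene_id"], frozenset({"TSS1500"})))
            elif g["gene_start"] <= posn <= g["gene_end"]:
                rows.append((probe["probe_id"], g["gene_id"], frozenset({"body"})))
    return ProbeAnnotation(pd.DataFrame(rows, columns=["probe_id", "gene_id", "region_tags"]))
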