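"""Orchestration of the two end-to-end workflows.

``run_pan_cancer`` goes from per-cancer count matrices to the pan-cancer
consensus network, its modular partition and per-(cancer, module) eigengene
scores: TMM-normalise each cancer and call DEGs vs normal, UQ-normalise the
combined tumor matrix, build per-cancer signed co-expression networks over
each cancer's DEGs, merge edges recurring in ≥ ``min_recurrence`` cancers,
partition the consensus by the leading-eigenvector method and score
modules. ``run_cancer_specific`` computes cross-cancer DE, specificity
scores, selects genes specific to each cancer among its DEGs-vs-normal and
extracts the largest connected component of a supplied interaction network
induced on them.

Both entry points consume in-memory objects (the io_formats readers load
them from disk) and record every threshold and the seed in a manifest dict
written alongside any outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .differential_expression import (
    de_vs_normal,
    de_vs_other_cancers,
    select_specific_genes,
    specificity_scores,
)
from .io_formats import ExpressionMatrix, SampleTable
from .module_detection import ModulePartition, leading_eigenvector_partition
from .module_scoring import ModuleScores, module_eigengene
from .network_construction import (
    CoexpressionNetwork,
    ConsensusNetwork,
    cancer_specific_subnetwork,
    consensus_network,
    largest_connected_component,
    pcc_matrix,
    threshold_edges,
)
from .normalization import filter_low_expressed, log_cpm, tmm_factors, uq_factors

__all__ = ["PipelineConfig", "PanCancerResult", "CancerSpecificResult", "run_pan_cancer", "run_cancer_specific"]


@dataclass
class PipelineConfig:
    """All thresholds of the workflow, with the published defaults."""

    fc_threshold: float = 2.0
    fdr: float = 0.001
    pan_p: float = 0.001
    cpm_floor: float = 10.0
    low_expr_frac: float = 0.5
    edge_q: float = 0.005
    min_recurrence: int = 3
    specificity_threshold: int = 8
    min_module_size: int = 10
    mutation_q: float = 0.1
    de_method: str = "welch"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr <= 1 and 0 < self.pan_p <= 1):
            raise ValueError("significance thresholds must lie in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fold-change threshold must be >= 1")
        if not 0 < self.edge_q < 1:
            raise ValueError("edge quota must lie in (0, 1)")
        if self.min_recurrence < 1 or self.min_module_size < 1:
            raise ValueError("count thresholds must be positive")

    def manifest(self, **extra) -> dict:
        m = asdict(self)
        m.update(extra)
        return m


@dataclass
class PanCancerResult:
    de_tables: dict[str, pd.DataFrame]
    networks: dict[str, CoexpressionNetwork]
    consensus: ConsensusNetwork
    partition: ModulePartition
    module_scores: dict[tuple[str, int], ModuleScores]
    logcpm_uq: ExpressionMatrix
    excluded_cancers: dict[str, str]
    manifest: dict

    def write_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=2, default=str))


@dataclass
class CancerSpecificResult:
    de_vs_others: pd.DataFrame
    specificity: pd.DataFrame
    specific_genes: dict[str, set[str]]
    subnetworks: dict[str, nx.Graph]
    module_scores: dict[str, ModuleScores]
    overlap_report: pd.DataFrame
    manifest: dict


def _uq_logcpm_tumors(
    counts: dict[str, ExpressionMatrix], sample_table: SampleTable
) -> ExpressionMatrix:
    """UQ-normalised logCPM of the combined tumor-only count matrix."""
    frames = []
    for c, mat in counts.items():
        tumors = [s for s in sample_table.samples(c, "tumor") if s in mat.values.columns]
        frames.append(mat.values[tumors])
    combined = pd.concat(frames, axis=1)
    combined = combined.dropna(axis=0)
    merged = ExpressionMatrix(combined, "counts")
    factors = uq_factors(merged)
    return log_cpm(merged, factors)


def run_pan_cancer(
    counts: dict[str, ExpressionMatrix],
    sample_table: SampleTable,
    config: PipelineConfig | None = None,
) -> PanCancerResult:
    """Counts → consensus network → modules → eigengene scores.

    ``counts`` maps cancer type → raw count matrix containing that
    cancer's tumor and normal samples. Cancers with fewer than five
    normals are excluded with a logged reason and the run continues;
    fewer than ``min_recurrence`` usable cancers is an error.
    """
    cfg = config or PipelineConfig()
    excluded: dict[str, str] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    high_expressed: dict[str, list[str]] = {}

    for c in sorted(counts):
        mat = counts[c]
        normals = [s for s in sample_table.samples(c, "normal") if s in mat.values.columns]
        if len(normals) < 5:
            excluded[c] = f"only {len(normals)} normal samples (need 5)"
            warnings.warn(f"{c} excluded: {excluded[c]}")
            continue
        factors = tmm_factors(mat)
        keep = filter_low_expressed(mat, factors, cfg.cpm_floor, cfg.low_expr_frac)
        high_expressed[c] = keep
        logcpm_tmm = log_cpm(mat.subset_genes(keep), factors)
        de_tables[c] = de_vs_normal(
            logcpm_tmm, sample_table, c,
            fc_threshold=cfg.fc_threshold, fdr=cfg.fdr, method=cfg.de_method,
        )

    if len(de_tables) < cfg.min_recurrence:
        raise RuntimeError(
            f"stage de_vs_normal: only {len(de_tables)} cancers usable, "
            f"need at least min_recurrence={cfg.min_recurrence}"
        )

    logcpm_uq = _uq_logcpm_tumors({c: counts[c] for c in de_tables}, sample_table)

    networks: dict[str, CoexpressionNetwork] = {}
    for c, de in de_tables.items():
        degs = [g for g in de.index[de["is_de"]] if g in logcpm_uq.values.index]
        tumors = [s for s in sample_table.samples(c, "tumor") if s in logcpm_uq.values.columns]
        if len(degs) < 2:
            warnings.warn(f"{c}: fewer than two DEGs, empty co-expression network")
            networks[c] = CoexpressionNetwork(c, {})
            continue
        grid = pcc_matrix(logcpm_uq.subset_samples(tumors), degs)
        networks[c] = threshold_edges(grid, q=cfg.edge_q, cancer_type=c)

    consensus = consensus_network(list(networks.values()), min_recurrence=cfg.min_recurrence)
    partition = leading_eigenvector_partition(consensus.graph(), min_size=cfg.min_module_size)

    module_scores: dict[tuple[str, int], ModuleScores] = {}
    for module_id, members in partition.modules().items():
        for c in de_tables:
            tumors = [s for s in sample_table.samples(c, "tumor") if s in logcpm_uq.values.columns]
            present = [g for g in sorted(members) if g in logcpm_uq.values.index]
            if len(present) < 2:
                continue
            sub = logcpm_uq.subset_samples(tumors)
            try:
                module_scores[(c, module_id)] = module_eigengene(
                    sub, present, module_id=module_id, cancer_type=c
                )
            except ValueError as err:
                warnings.warn(f"module {module_id} in {c}: {err}")

    manifest = cfg.manifest(
        stage="pan_cancer",
        cancers=sorted(de_tables),
        excluded=excluded,
        n_consensus_edges=len(consensus.edges),
        n_modules=len(partition.modules()),
        modularity_q=partition.q,
    )
    return PanCancerResult(
        de_tables, networks, consensus, partition, module_scores, logcpm_uq, excluded, manifest
    )


def run_cancer_specific(
    counts: dict[str, ExpressionMatrix],
    sample_table: SampleTable,
    interaction_network: nx.Graph | pd.DataFrame,
    config: PipelineConfig | None = None,
    pan_result: PanCancerResult | None = None,
) -> CancerSpecificResult:
    """Cross-cancer DE → specificity → specific subnetworks → eigengenes.

    Reuses the vs-normal DE tables and UQ logCPM of ``pan_result`` when
    given, otherwise recomputes them via :func:`run_pan_cancer`.
    """
    cfg = config or PipelineConfig()
    if pan_result is None:
        pan_result = run_pan_cancer(counts, sample_table, cfg)
    logcpm_uq = pan_result.logcpm_uq

    labels = pd.Series(
        {
            s: c
            for c in pan_result.de_tables
            for s in sample_table.samples(c, "tumor")
            if s in logcpm_uq.values.columns
        }
    )
    high = {
        c: [g for g in de.index if g in logcpm_uq.values.index]
        for c, de in pan_result.de_tables.items()
    }
    de_others = de_vs_other_cancers(
        logcpm_uq, labels,
        p_threshold=cfg.pan_p, fc_threshold=cfg.fc_threshold, high_expressed=high,
    )
    spec = specificity_scores(de_others)
    specific = select_specific_genes(spec, pan_result.de_tables, cfg.specificity_threshold)

    subnetworks: dict[str, nx.Graph] = {}
    scores: dict[str, ModuleScores] = {}
    skipped: dict[str, str] = {}
    for c, genes in specific.items():
        if not genes:
            skipped[c] = "empty specific gene set"
            continue
        sub = cancer_specific_subnetwork(genes, interaction_network)
        if sub.number_of_nodes() == 0:
            skipped[c] = "no connected specific genes in the interaction network"
            continue
        subnetworks[c] = sub
        tumors = [s for s in sample_table.samples(c, "tumor") if s in logcpm_uq.values.columns]
        present = [g for g in sorted(sub.nodes) if g in logcpm_uq.values.index]
        if len(present) >= 2:
            scores[c] = module_eigengene(
                logcpm_uq.subset_samples(tumors), present, module_id=f"{c}_specific", cancer_type=c
            )

    cancers = sorted(specific)
    overlap_rows = []
    for i, a in enumerate(cancers):
        for b in cancers[i + 1:]:
            inter = len(specific[a] & specific[b])
            union = len(specific[a] | specific[b])
            overlap_rows.append((a, b, len(specific[a]), len(specific[b]), inter,
                                 inter / union if union else 0.0))
    overlap_report = pd.DataFrame(
        overlap_rows, columns=["cancer_a", "cancer_b", "n_a", "n_b", "overlap", "jaccard"]
    )

    manifest = cfg.manifest(
        stage="cancer_specific",
        cancers=cancers,
        skipped=skipped,
        subnetwork_sizes={c: g.number_of_nodes() for c, g in subnetworks.items()},
    )
    return CancerSpecificResult(de_others, spec, specific, subnetworks, scores, overlap_report, manifest)
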