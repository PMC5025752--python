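"""Synthetic multi-cancer cohorts with planted, fully known structure.

The generator emulates the data model the pipeline assumes, so every stage
is testable without external downloads:

* negative-binomial gene-level counts on a log-linear latent-factor model,
  with log-normal library-size variation;
* planted co-expressed gene blocks ("shared modules") active in a subset of
  ≥3 cancers and one private module per cancer, both driven by a standard
  normal per-sample factor — the true module eigengene;
* planted tumor-vs-normal log2 fold changes (module genes plus a random
  per-cancer background fraction) and cancer-vs-cancer marker effects on
  the private module genes;
* mutation, copy-number, promoter-methylation, clinical-group and survival
  signals coupled to the true module activity;
* a planted interaction network whose densely wired blocks are the private
  modules (standing in for a curated external network).

Ground truth (module labels, DE flags, coupled genes, per-sample factors)
is returned alongside the data, never re-derived. All randomness flows
from one integer seed; the same seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneModel, ProbeAnnotation, SampleTable

__all__ = ["SyntheticConfig", "GroundTruth", "generate_cohort", "generate_omics"]


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    Defaults describe a 4-cancer desk-scale cohort: 60 tumors + 10 normals
    per cancer, 2000 genes, four 40-gene shared modules each active in 3
    cancers (factor effect β=1.2 on log2 expression), one 30-gene private
    module per cancer, half of the background genes differentially
    expressed per cancer with |log2FC| in [1.5, 3]. The generous DE
    background keeps the per-cancer DEG networks near a thousand nodes, so
    the top-0.5% edge quota comfortably covers the planted module pairs —
    mirroring how module edges survive thresholding in cohorts of this
    design.
    """

    n_cancers: int = 4
    tumors_per_cancer: int = 60
    normals_per_cancer: int = 10
    n_genes: int = 2000

    n_shared_modules: int = 4
    shared_module_size: int = 40
    shared_module_cancers: int = 3  # each shared module is active in this many cancers
    shared_module_beta: float = 1.2  # log2-scale loading on the latent factor

    private_module_size: int = 30
    private_module_beta: float = 1.2

    de_fraction: float = 0.5  # background genes DE vs normal, per cancer
    de_log2fc_range: tuple[float, float] = (1.5, 3.0)
    module_de_log2fc: float = 2.0  # shared-module genes, tumor vs normal
    marker_log2fc: float = 3.0  # private-module genes in the owner cancer

    nb_dispersion: float = 0.15
    baseline_log2_range: tuple[float, float] = (4.0, 10.0)
    lib_size_log_mean: float = np.log(8e5)
    lib_size_log_sd: float = 0.3

    # omics couplings
    mutation_intercept: float = -1.0
    mutation_coupling: float = 2.0  # logit slope on the true factor
    scna_coupling: float = 0.5  # dosage per unit of private factor
    scna_noise_sd: float = 0.1
    meth_coupling: float = 0.35  # promoter β logit slope (negative on expression)
    meth_noise_sd: float = 0.5
    survival_log_hr: float = float(np.log(3.0))  # high- vs low-activity hazard ratio
    survival_baseline_hazard: float = 1.0 / 800.0  # per day
    censor_horizon: float = 2000.0  # uniform censoring upper bound, days
    clinical_label_noise: float = 0.1

    seed: int = 0

    def __post_init__(self) -> None:
        if self.normals_per_cancer < 5:
            raise ValueError("need at least five normal samples per cancer")
        if self.shared_module_size < 2 or self.private_module_size < 2:
            raise ValueError("module sizes must be at least 2")
        if self.shared_module_cancers < 3:
            raise ValueError("shared modules must span at least three cancers")
        if self.shared_module_cancers > self.n_cancers:
            raise ValueError("shared_module_cancers exceeds n_cancers")
        n_planted = (
            self.n_shared_modules * self.shared_module_size
            + self.n_cancers * self.private_module_size
        )
        if n_planted >= self.n_genes:
            raise ValueError("planted modules exceed the gene count")

    @property
    def cancer_types(self) -> list[str]:
        return [f"C{i+1}" for i in range(self.n_cancers)]


@dataclass
class GroundTruth:
    """Everything planted: labels, flags, couplings and true factors."""

    shared_modules: dict[str, list[str]]  # module name -> gene ids
    shared_module_cancers: dict[str, list[str]]
    private_modules: dict[str, list[str]]  # cancer -> gene ids
    de_vs_normal: dict[str, set[str]]  # cancer -> genes with planted tumor offsets
    marker_genes: dict[str, set[str]]  # cancer -> genes planted as cancer-specific
    factors: pd.DataFrame  # tumor sample × module true activity (NaN if inactive)
    interaction_edges: pd.DataFrame  # gene_a, gene_b
    mutation_drivers: dict[str, dict[str, str]] = field(default_factory=dict)
    scna_blocks: dict[str, list[str]] = field(default_factory=dict)
    meth_coupled: dict[str, list[str]] = field(default_factory=dict)
    prognostic_module: dict[str, str] = field(default_factory=dict)

    def shared_gene_labels(self) -> pd.Series:
        out = {}
        for name, genes in self.shared_modules.items():
            for g in genes:
                out[g] = name
        return pd.Series(out, name="module")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[dict[str, ExpressionMatrix], SampleTable, GroundTruth]:
    """Draw count matrices, the sample table and the planted ground truth.

    Per sample, a standard-normal latent factor is drawn for each planted
    module active in its cancer (tumor samples only); the log2 mean of gene
    g is its baseline plus β·factor when g belongs to the module, plus
    tumor-only differential-expression offsets. Counts are negative
    binomial around the library-scaled means. The first
    ``normals_per_cancer`` patients of each cancer contribute both a tumor
    and a normal sample (matched-normal design).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = _gene_ids(cfg.n_genes)
    cancers = cfg.cancer_types

    # --- planted gene blocks (disjoint) -------------------------------
    cursor = 0
    shared_modules: dict[str, list[str]] = {}
    shared_cancers: dict[str, list[str]] = {}
    for m in range(cfg.n_shared_modules):
        shared_modules[f"M{m+1}"] = genes[cursor : cursor + cfg.shared_module_size]
        cursor += cfg.shared_module_size
        shared_cancers[f"M{m+1}"] = [
            cancers[(m + j) % cfg.n_cancers] for j in range(cfg.shared_module_cancers)
        ]
    private_modules: dict[str, list[str]] = {}
    for c in cancers:
        private_modules[c] = genes[cursor : cursor + cfg.private_module_size]
        cursor += cfg.private_module_size
    background = genes[cursor:]

    baseline = rng.uniform(*cfg.baseline_log2_range, size=cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # --- tumor-vs-normal offsets per cancer ---------------------------
    offsets = {c: np.zeros(cfg.n_genes) for c in cancers}
    de_truth: dict[str, set[str]] = {c: set() for c in cancers}
    for name, members in shared_modules.items():
        for c in shared_cancers[name]:
            for g in members:
                offsets[c][gene_pos[g]] += cfg.module_de_log2fc
            de_truth[c].update(members)
    for c in cancers:
        for g in private_modules[c]:
            offsets[c][gene_pos[g]] += cfg.marker_log2fc
        de_truth[c].update(private_modules[c])
        n_bg = int(round(cfg.de_fraction * len(background)))
        chosen = rng.choice(len(background), size=n_bg, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_bg)
        mags = rng.uniform(*cfg.de_log2fc_range, size=n_bg)
        for idx, sgn, mag in zip(chosen, signs, mags):
            g = background[idx]
            offsets[c][gene_pos[g]] += sgn * mag
            de_truth[c].add(g)

    module_names = list(shared_modules) + [f"private_{c}" for c in cancers]
    active_in = {name: set(shared_cancers[name]) for name in shared_modules}
    for c in cancers:
        active_in[f"private_{c}"] = {c}
    loadings = {name: np.zeros(cfg.n_genes) for name in module_names}
    for name, members in shared_modules.items():
        for g in members:
            loadings[name][gene_pos[g]] = cfg.shared_module_beta
    for c in cancers:
        for g in private_modules[c]:
            loadings[f"private_{c}"][gene_pos[g]] = cfg.private_module_beta

    # --- draw samples --------------------------------------------------
    counts: dict[str, ExpressionMatrix] = {}
    sample_rows = []
    factor_rows = {}
    disp = cfg.nb_dispersion
    r_nb = 1.0 / disp if disp > 0 else None
    for c in cancers:
        cols = {}
        for t in range(cfg.tumors_per_cancer):
            patient = f"{c}-P{t:03d}"
            sample = f"{c}-P{t:03d}-T"
            sample_rows.append((sample, patient, c, "tumor"))
            x = baseline + offsets[c]
            fs = {}
            for name in module_names:
                if c in active_in[name]:
                    f = rng.standard_normal()
                    fs[name] = f
                    x = x + loadings[name] * f
            factor_rows[sample] = fs
            cols[sample] = _draw_counts(x, cfg, rng, r_nb)
        for t in range(cfg.normals_per_cancer):
            patient = f"{c}-P{t:03d}"
            sample = f"{c}-P{t:03d}-N"
            sample_rows.append((sample, patient, c, "normal"))
            cols[sample] = _draw_counts(baseline, cfg, rng, r_nb)
        counts[c] = ExpressionMatrix(pd.DataFrame(cols, index=genes), "counts")

    sample_table = SampleTable(
        pd.DataFrame(sample_rows, columns=["sample_id", "patient_id", "cancer_type", "tissue_status"])
    )
    factors = pd.DataFrame.from_dict(factor_rows, orient="index").reindex(columns=module_names)

    interaction_edges = _interaction_network(cfg, private_modules, genes, rng)
    marker = {c: set(private_modules[c]) for c in cancers}
    truth = GroundTruth(
        shared_modules=shared_modules,
        shared_module_cancers=shared_cancers,
        private_modules=private_modules,
        de_vs_normal=de_truth,
        marker_genes=marker,
        factors=factors,
        interaction_edges=interaction_edges,
    )
    return counts, sample_table, truth


def _draw_counts(log2_mean, cfg: SyntheticConfig, rng, r_nb):
    w = np.exp2(log2_mean)
    lib = float(np.exp(rng.normal(cfg.lib_size_log_mean, cfg.lib_size_log_sd)))
    mu = lib * w / w.sum()
    if r_nb is None:
        return rng.poisson(mu)
    p = r_nb / (r_nb + mu)
    return rng.negative_binomial(r_nb, p)


def _interaction_network(cfg, private_modules, genes, rng, p_within=0.3, n_background=600):
    """Planted interaction edges: dense wiring inside each private module
    plus a sparse (subcritical) random background over all genes."""
    edges = set()
    for members in private_modules.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < p_within:
                    edges.add(tuple(sorted((members[i], members[j]))))
    n = len(genes)
    drawn = 0
    while drawn < n_background:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        pair = tuple(sorted((genes[i], genes[j])))
        if pair not in edges:
            edges.add(pair)
            drawn += 1
    return pd.DataFrame(sorted(edges), columns=["gene_a", "gene_b"])


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def generate_omics(
    config: SyntheticConfig,
    counts: dict[str, ExpressionMatrix],
    sample_table: SampleTable,
    truth: GroundTruth,
    seed: int | None = None,
) -> dict:
    """Draw mutation, SCNA, methylation and clinical/survival tables
    coupled to the planted module activities.

    * Mutation: per cancer, one driver gene per active shared module;
      P(mutant) = logistic(a + b·f) with f the patient's true factor. The
      q table marks drivers (q=0.001), a few retained passengers (q=0.05)
      and a few filtered genes (q=0.5).
    * SCNA: segments partition each chromosome; in the owner cancer the
      private-module block's tumor dosage is ``scna_coupling``·f plus
      noise, normals sit near zero.
    * Methylation: promoter probes of the coupled genes follow
      β = logistic(−``meth_coupling``·(logexpr − mean) + noise) — higher
      expression, lower promoter methylation; body probes and uncoupled
      genes are noise.
    * Clinical/survival: exponential survival with hazard multiplied by
      exp(log-HR) for patients with above-median prognostic-module
      activity, uniform censoring; a stage label cut from factor quartiles
      with label noise.

    Returns a dict with keys ``mutations`` (cancer → table), ``q_tables``,
    ``segments``, ``gene_model``, ``beta`` (matrix), ``probe_annotation``,
    ``clinical`` and updates ``truth`` in place with the coupled entities.
    """
    cfg = config
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1_000_003)
    cancers = cfg.cancer_types
    genes = _gene_ids(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    tumor_samples = {c: sample_table.samples(c, "tumor") for c in cancers}
    patient_of = sample_table.patient_of()

    # ------------------------------------------------ mutations -------
    mutations: dict[str, pd.DataFrame] = {}
    q_tables: dict[str, pd.DataFrame] = {}
    for c in cancers:
        active_shared = [m for m, cs in truth.shared_module_cancers.items() if c in cs]
        drivers = {}
        rows = []
        for m in active_shared:
            # driver = first member gene of the module, a bookkeeping choice
            gene = truth.shared_modules[m][0]
            drivers[gene] = m
            f = truth.factors.loc[tumor_samples[c], m].to_numpy()
            p_mut = _logistic(cfg.mutation_intercept + cfg.mutation_coupling * f)
            status = rng.random(len(f)) < p_mut
            for s, mut in zip(tumor_samples[c], status):
                rows.append((patient_of[s], gene, "mutant" if mut else "wild_type", 0.001))
        passengers = [g for g in genes[-10:]]
        for i, g in enumerate(passengers[:5]):
            p_mut = 0.2
            status = rng.random(len(tumor_samples[c])) < p_mut
            for s, mut in zip(tumor_samples[c], status):
                rows.append((patient_of[s], g, "mutant" if mut else "wild_type", 0.05))
        mutations[c] = pd.DataFrame(rows, columns=["patient_id", "gene_id", "status", "q_value"])
        q_rows = [(g, 0.001) for g in drivers] + [(g, 0.05) for g in passengers[:5]]
        q_rows += [(g, 0.5) for g in passengers[5:]]
        q_tables[c] = pd.DataFrame(q_rows, columns=["gene_id", "q_value"])
        truth.mutation_drivers[c] = drivers

    # ------------------------------------------------ SCNA ------------
    genes_per_chrom = 200
    gm_rows = []
    for i, g in enumerate(genes):
        chrom = str(i // genes_per_chrom + 1)
        start = 1 + (i % genes_per_chrom) * 10_000
        end = start + 5_000
        gm_rows.append((g, chrom, "+", start, start + 500, start, end))
    gene_model = GeneModel(
        pd.DataFrame(
            gm_rows,
            columns=["gene_id", "chromosome", "strand", "tss", "first_exon_end", "gene_start", "gene_end"],
        )
    )
    chrom_len = genes_per_chrom * 10_000 + 10_000

    seg_rows = []
    for c in cancers:
        block = truth.private_modules[c]
        idx_all = sorted(gene_pos[g] for g in block)
        # keep the block on a single chromosome so its segment is valid and
        # every coupled gene is fully contained
        b_chrom_i = idx_all[0] // genes_per_chrom
        idx = [i for i in idx_all if i // genes_per_chrom == b_chrom_i]
        b_chrom = str(b_chrom_i + 1)
        b_start = 1 + (idx[0] % genes_per_chrom) * 10_000
        b_end = 1 + (idx[-1] % genes_per_chrom) * 10_000 + 5_000
        truth.scna_blocks[c] = [genes[i] for i in idx]
        matched = sample_table.table[
            (sample_table.table["cancer_type"] == c)
        ]
        for _, row in matched.iterrows():
            s = row["sample_id"]
            is_tumor = row["tissue_status"] == "tumor"
            n_chroms = (cfg.n_genes - 1) // genes_per_chrom + 1
            for ch in range(1, n_chroms + 1):
                chrom = str(ch)
                base = rng.normal(0.0, 0.03)
                if chrom == b_chrom and is_tumor:
                    f = truth.factors.loc[s, f"private_{c}"]
                    dosage = cfg.scna_coupling * f + rng.normal(0.0, cfg.scna_noise_sd)
                    if b_start > 1:
                        seg_rows.append((s, chrom, 1, b_start - 1, base))
                    seg_rows.append((s, chrom, b_start, b_end, dosage))
                    if b_end < chrom_len:
                        seg_rows.append((s, chrom, b_end + 1, chrom_len, rng.normal(0.0, 0.03)))
                else:
                    seg_rows.append((s, chrom, 1, chrom_len, base))
    segments = (
        pd.DataFrame(seg_rows, columns=["sample_id", "chromosome", "start", "end", "seg_mean"])
        .sort_values(["sample_id", "chromosome", "start"], kind="mergesort")
        .reset_index(drop=True)
    )

    # ------------------------------------------------ methylation -----
    coupled = truth.shared_modules["M1"]
    for c in cancers:
        truth.meth_coupled[c] = list(coupled)
    uncoupled = genes[-40:]
    probe_rows = []
    for g in list(coupled) + list(uncoupled):
        probe_rows.append((f"cg_{g}_p1", g, frozenset({"TSS200"})))
        probe_rows.append((f"cg_{g}_p2", g, frozenset({"TSS1500", "body"})))
        probe_rows.append((f"cg_{g}_b", g, frozenset({"body"})))
    probe_annotation = ProbeAnnotation(
        pd.DataFrame(probe_rows, columns=["probe_id", "gene_id", "region_tags"])
    )
    all_tumors = [s for c in cancers for s in tumor_samples[c]]
    beta_rows = {}
    logexpr = {}
    for c in cancers:
        lib = counts[c].values.sum(axis=0)
        le = np.log2(counts[c].values / lib * 1e6 + 0.5)
        for s in tumor_samples[c]:
            logexpr[s] = le[s]
    for probe_id, g, tags in probe_rows:
        vals = []
        for s in all_tumors:
            if g in coupled and (tags & {"TSS200", "TSS1500"}):
                x = logexpr[s][g]
                z = -cfg.meth_coupling * (x - 6.0) + rng.normal(0.0, cfg.meth_noise_sd)
                vals.append(_logistic(z))
            else:
                vals.append(float(rng.beta(2.0, 2.0)))
        beta_rows[probe_id] = vals
    beta = ExpressionMatrix(
        pd.DataFrame.from_dict(beta_rows, orient="index", columns=all_tumors), "beta"
    )

    # ------------------------------------------------ clinical --------
    clin_rows = []
    for c in cancers:
        active_shared = [m for m, cs in truth.shared_module_cancers.items() if c in cs]
        prog = active_shared[0]
        truth.prognostic_module[c] = prog
        f = truth.factors.loc[tumor_samples[c], prog]
        high = f > f.median()
        hazard = cfg.survival_baseline_hazard * np.where(high, np.exp(cfg.survival_log_hr), 1.0)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.uniform(0, cfg.censor_horizon, size=len(f))
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
        quart = pd.qcut(f, 4, labels=["T1", "T2", "T3", "T4"]).astype(str)
        noise = rng.random(len(f)) < cfg.clinical_label_noise
        stages = np.where(noise, rng.choice(["T1", "T2", "T3", "T4"], size=len(f)), quart)
        for s, ti, ev, st in zip(tumor_samples[c], time, event, stages):
            clin_rows.append((patient_of[s], c, st, float(ti), bool(ev)))
    clinical = pd.DataFrame(
        clin_rows, columns=["patient_id", "cancer_type", "stage", "survival_time", "survival_event"]
    )

    return {
        "mutations": mutations,
        "q_tables": q_tables,
        "segments": segments,
        "gene_model": gene_model,
        "beta": beta,
        "probe_annotation": probe_annotation,
        "clinical": clinical,
    }
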