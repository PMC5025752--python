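# Methods

`panconet` implements a pan-cancer transcriptome workflow that goes from
per-cancer RNA-seq count matrices to (i) a consensus co-expression network
and its modular decomposition, and (ii) cancer-type-specific subnetworks,
with module-activity scores tested against mutations, copy number, promoter
methylation, clinical groups and survival. This note records the models,
the parameters that matter, the numerical conventions, and what the
synthetic cohort does and does not show.

## Normalization

Two library-size scalings are provided, used in different places:

* **TMM** (trimmed mean of M-values) assumes most genes are not
  differentially expressed. The reference sample is the one whose
  75th-percentile count fraction is closest to the mean of that quantity.
  For each sample against the reference, per-gene log-ratios
  M_g = log2((y_gs/N_s)/(y_gr/N_r)) and abundances
  A_g = ½·log2(y_gs·y_gr/(N_s·N_r)) are computed over genes expressed in
  both; the most extreme 30 % of M and 5 % of A are trimmed symmetrically
  by rank, and the factor is 2 to the weighted mean of the surviving M,
  with inverse-asymptotic-variance weights
  (N_s−y_gs)/(N_s·y_gs) + (N_r−y_gr)/(N_r·y_gr). TMM is used for the
  within-cancer tumor-vs-normal contrast.
* **UQ** (upper quartile) divides each library by its 75th-percentile
  count over genes with nonzero total — a weaker assumption suitable for
  the combined matrix of thousands of tumors from many lineages, where
  TMM's majority-null assumption is strained. UQ is used for the combined
  cross-cancer matrix, the co-expression networks and all eigengene
  scores.

Both factor sets are rescaled to geometric mean 1. Percentiles use the
linear-interpolation (type-7) definition throughout — the most common
default, declared to make results bit-stable. log-CPM adds a prior count
of +0.5 to each observation inside the log
(value = log2((y+0.5)/(N_s·f_s)·10⁶)), so a zero count at effective
library size 10⁶ maps to exactly −1. The low-expression filter removes a
gene when strictly more than half of samples have CPM < 10 (no prior in
the CPM used for filtering); a gene at exactly half is kept.

## Differential expression

*Versus normal*, per cancer (requires ≥5 normal samples): Welch's t test
(Satterthwaite df) per gene on TMM logCPM, BH-adjusted; a gene is a DEG at
|Δ logCPM| ≥ 1 (fold change ≥ 2, the fold change being the difference of
group means on the log scale) and adjusted p ≤ 0.001. A `moderated` mode
replaces per-gene pooled variances with empirical-Bayes posterior
variances s̃²_g = (d₀s₀² + d·s²_g)/(d₀+d), where (d₀, s₀²) are fitted by
moment-matching the distribution of log s²_g (digamma/trigamma identities,
trigamma inverted by Newton iteration) and the t statistic gains d₀
degrees of freedom. The moderated mode uses the pooled two-group variance
with a common residual df — the classic setting for variance shrinkage;
the Welch mode keeps per-gene df.

*Versus other cancers*: each target cancer's tumors are Welch-tested
against every other cancer's tumors per gene on the combined UQ logCPM,
and the p values are Bonferroni-corrected over the target's whole family —
all tested genes × all other cancers jointly, not per comparison. A gene
is tested for a pair only when it is high-expressed in both cancers;
untested genes contribute no flag and do not enter the family. Flags need
adjusted p ≤ 0.001 and fold change ≥ 2.

The **specificity** of a (gene, cancer) pair counts the other cancers the
gene is flagged against. A gene is *specific* to a cancer when it is a DEG
vs normal there and its specificity is **no less than** a configurable
threshold (equality qualifies). The default threshold is 8 for a 16-cancer
cohort; for the 4-cancer synthetic cohort the analogous choice is
n_cancers − 1 = 3 ("specific against every other cancer"), which the
synthetic workflow passes explicitly.

## Networks and modules

Per cancer, Pearson correlations are computed between that cancer's
DEGs-vs-normal over **tumor samples only** on UQ logCPM (tumor-only is our
reading of the workflow: normals would otherwise dominate the correlation
structure through the tumor/normal contrast itself). With n genes,
k = floor(0.005·C(n,2)) pairs are kept per sign: the k most positive as
'+' edges and the k most negative as '−' edges; ties break by canonical
(lexicographic) pair order, a pair qualifying for both lists keeps '+',
and isolated nodes are dropped. The floor rule makes "top 0.5 %" an
integer deterministically and conservatively.

The consensus network keeps pairs recurring in at least `min_recurrence`
per-cancer networks (default 3 with ≥ semantics; a strict sign-matching
mode counts the best single-sign recurrence instead). Sign agreement
across contributing cancers is recorded per edge.

Modules come from Newman's leading-eigenvector method: recursively, the
dominant eigenvector of the (generalized) modularity matrix
B_ij = A_ij − k_i·k_j/(2m), restricted to the group with row-sum diagonal
correction B^(g)_ij = B_ij − δ_ij·Σ_{k∈g} B_ik, splits nodes by component
sign (zero components join '+'); a group is indivisible when the leading
eigenvalue is ≤ 1e−10 or the split's ΔQ = s^T B^(g) s/(4m) is ≤ 0. Edge
signs are bookkeeping: the partition runs on the unweighted, unsigned
topology. Determinism is guaranteed by fixing the eigenvector sign (the
lexicographically smallest node's component is ≥ 0). No Kernighan–Lin
refinement is applied in v1. Final modules smaller than `min_module_size`
(default 10) are relabeled −1 — the "few exceptional nodes" rule, which
the source workflow leaves unquantified; in `modularity_Q` such nodes are
scored as singleton modules so the reported Q is self-consistent with the
returned labels.

## Module scores

The module eigengene (ME) is the first principal component of the module's
logCPM submatrix over a cancer's tumor samples, computed on the covariance
matrix (genes centered, no variance scaling, so high-variance genes weigh
more). Module membership (MM) is each gene's Pearson correlation with the
ME; var_explained is λ₁/Σλ. The component sign is chosen so that the
majority of genes have positive MM (ties: the lexicographically smallest
gene's MM ≥ 0) — an orientation must be fixed somewhere and this one makes
"module up" mean "most member genes up". Patients are split into low/high
groups at the median ME; ties at the median go to the low group.

## Genomic mapping

* **SCNA**: a gene gets a segment's mean only when its full span is
  contained in exactly one segment of that sample (1-based inclusive on
  both sides); straddling, uncovered or doubly-contained genes are
  missing (ambiguity is treated as absence of a unique value). Genes
  missing in strictly more than half of samples are dropped; the rest are
  imputed (below). Patient-level somatic values are the tumor sample minus
  the mean of that patient's normals; patients with more than one tumor
  sample or no normal are excluded.
* **kNN imputation** (k = 10): neighbors are *gene rows*, ranked by
  Euclidean distance over columns observed in both rows, rescaled by
  √(n_columns/n_shared). The imputed value is the mean of the k nearest
  genes observed at that sample; nearer genes lacking a value there are
  skipped for the next nearest, and a row mean is the last resort.
  Row-versus-column neighbors and the rescaling are our declared choices
  for this expression-like setting. Observed entries are never altered.
* **Promoter methylation**: a probe counts toward a gene's promoter when
  any of its region tags is TSS1500, TSS200, 5'UTR or first exon
  (1500 bp upstream of the TSS through the first exon); gene-level β is
  the mean of those probes per sample. A coordinate-based, strand-aware
  fallback derives tags from a gene model when the annotation lacks them.

## Association battery

Mann–Whitney U (two-sided) compares ME between mutant and wild-type
patients per significantly mutated gene (q < 0.1 upstream; both groups
need ≥ 3 patients, a guard for degenerate splits), BH-corrected per
eigengene. Exact enumeration is used when n₁+n₂ ≤ 12 and the data are
tie-free (cheap and exact), otherwise the tie-corrected normal
approximation with continuity correction. Pearson correlation (p by the
exact t transform on n−2 df) links ME to gene-level SCNA and promoter β.
Clinical groups use Kruskal–Wallis for > 2 groups and Mann–Whitney for 2.
Survival uses Kaplan–Meier curves of the median-split ME groups and the
two-group log-rank test (χ², 1 df). Gene-set enrichment is the one-sided
hypergeometric tail (over-representation, the usual enrichment
convention; a two-sided Fisher mode exists but is off by default), BH
across sets. Families for BH are defined per (module, data modality); raw
and adjusted p are always both reported.

Degenerate-input conventions: identical constant groups give p = 1 (Welch,
Kruskal–Wallis); a dead-centre Mann–Whitney statistic gives p = 1;
constant input to Pearson is an error rather than a silent NaN.

## Synthetic cohort

The generator plants everything the pipeline is supposed to find. Counts
are negative binomial (dispersion 0.15) around library-scaled means
(log-normal library sizes, σ = 0.3 around 8×10⁵); gene baselines are
uniform on log2 [4, 10]. Per tumor sample, each planted module active in
its cancer contributes β·f to member genes' log2 means, with f ~ N(0,1)
the true module activity. Defaults: 4 cancers × 60 tumors + 10 matched
normals, 2000 genes, four 40-gene shared modules each active in 3 cancers
(β = 1.2), one 30-gene private module per cancer (β = 1.2, +3 log2 in
owner tumors), shared-module genes +2 log2 in member-cancer tumors, and
half of the background genes DE per cancer with |log2FC| uniform on
[1.5, 3].

The generous background DE fraction is a structural requirement, not a
flourish: per-cancer networks keep only floor(0.005·C(n,2)) edges per
sign, so the ~2.3k planted module pairs can all survive thresholding in
every member cancer only when the DEG network has on the order of 10³
nodes. At these settings module pairs correlate at r ≈ 0.8 against a null
spread of ≈ 0.13, so thresholding keeps essentially all of them and the
consensus (recurrence ≥ 3) is dominated by the planted blocks.

Coupled omics: mutation status is Bernoulli(logistic(−1 + 2f)) for one
driver gene per active shared module; the private-module block gets a
per-sample copy-number dosage 0.5·f plus noise in owner tumors (segments
partition each synthetic chromosome, so containment is unambiguous);
promoter β of coupled genes is logistic in −0.35·(logexpr−6) plus noise;
survival is exponential with hazard ×3 for above-median prognostic-module
activity under uniform censoring at 2000 days; a stage label cuts the
factor into quartiles with 10 % label noise.

What the synthetic cohort does **not** emulate: batch effects, tumor
purity and subclonality, multimodal expression (mixtures of subtypes
within one label), gene length or GC bias, correlated module overlap, and
realistic mutation spectra. Passing the planted-recovery tests shows the
pipeline's machinery is correct and calibrated under its own modeling
assumptions; it does not certify performance on real cohorts, where those
unmodeled features dominate the hard cases.

## Problem sizes and determinism

The validation suite runs the full two-branch pipeline over 20 cohort
seeds at the default scale above, plus calibration simulations (200 null
DE cohorts of 2000 genes; 1000 null log-rank replicates; 300 permutation
replicates of the mutation test) — sizes chosen so the whole suite
completes in a couple of minutes on one CPU while keeping Monte-Carlo
error well inside the asserted margins. All randomness flows through
integer seeds into `numpy.random.default_rng`; tie rules (canonical pair
order, eigenvector sign, median-split low side) are fixed so same-seed
reruns are identical.

## Known limitations

* The leading-eigenvector implementation is dense; networks with more
  than a few thousand nodes would want a sparse eigensolver.
* No Cox regression or multivariate survival adjustment (by design: the
  workflow uses only KM + log-rank).
* The specificity threshold for real 16-cancer cohorts is a required
  configuration choice; no value is asserted as canonical.
* `de_vs_other_cancers` materialises one long row per tested
  (gene, target, other) triple; fine at 10⁴–10⁵ tests, wasteful beyond.
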