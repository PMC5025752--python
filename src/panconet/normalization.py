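"""Library-size normalization for RNA-seq count matrices.

Two scaling strategies are provided. The trimmed mean of M-values (TMM)
assumes most genes are not differentially expressed and estimates, for each
sample against a reference, a robust weighted mean of per-gene log-ratios
after trimming extremes in both the log-ratio (M) and abundance (A)
dimensions. Upper-quartile (UQ) scaling divides each library by its 75th
percentile count over expressed genes — a weaker assumption suited to large
heterogeneous sample collections. TMM is the natural choice within one
tissue (tumor vs matched normal contrasts); UQ for a combined matrix of
thousands of tumors from many lineages.

Both produce factors rescaled to geometric mean 1, so the effective library
size is ``library_size × factor``. Counts-per-million and log2-CPM use the
effective library size with a +0.5 prior count added to each observation
inside the log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix

__all__ = [
    "NormalizationFactors",
    "tmm_factors",
    "uq_factors",
    "cpm",
    "log_cpm",
    "filter_low_expressed",
]


@dataclass
class NormalizationFactors:
    """Per-sample scaling factors with geometric mean 1."""

    factors: pd.Series  # indexed by sample id
    method: str  # "tmm" | "uq" | "none"
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        log_gm = np.log(self.factors.to_numpy()).mean()
        if abs(log_gm) > 1e-8:
            raise ValueError("factors must have geometric mean 1")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def _rescale_geomean(f: np.ndarray) -> np.ndarray:
    return f / np.exp(np.log(f).mean())


def _require_counts(counts: ExpressionMatrix) -> np.ndarray:
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit={counts.unit!r}")
    return counts.values.to_numpy(dtype=float)


def identity_factors(counts: ExpressionMatrix) -> NormalizationFactors:
    y = _require_counts(counts)
    n = y.sum(axis=0)
    return NormalizationFactors(
        pd.Series(np.ones(y.shape[1]), index=counts.sample_ids), "none",
        pd.Series(n, index=counts.sample_ids),
    )


def _tmm_pair(y_s, y_r, n_s, n_r, trim_m, trim_a):
    """Trimmed, inverse-variance-weighted mean of M values for one sample
    against the reference; returns the log2 scaling factor."""
    ok = (y_s > 0) & (y_r > 0)
    if not ok.any():
        raise ValueError("sample shares no expressed gene with the TMM reference")
    ys, yr = y_s[ok], y_r[ok]
    m = np.log2((ys / n_s) / (yr / n_r))
    a = 0.5 * np.log2((ys / n_s) * (yr / n_r))
    # binomial asymptotic variance of M
    v = (n_s - ys) / (n_s * ys) + (n_r - yr) / (n_r * yr)
    if np.max(np.abs(m)) < 1e-6:  # identical relative profiles
        return 0.0
    n = m.size
    # double trim by rank, mirroring the usual keep-rule
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    return float(np.sum(w * m[keep]) / np.sum(w))


def tmm_factors(
    counts: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of that quantity across samples. For every other
    sample, per-gene log-ratios M and average abundances A are computed
    over genes expressed in both libraries, the most extreme 30% of M and
    5% of A are trimmed symmetrically, and the factor is 2 to the
    inverse-asymptotic-variance weighted mean of the surviving M values.
    Factors are rescaled to geometric mean 1.
    """
    y = _require_counts(counts)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample in count matrix")
    f75 = np.array([np.percentile(y[:, j], 75) for j in range(y.shape[1])]) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    log_f = np.array([
        0.0 if j == ref else _tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref], trim_m, trim_a)
        for j in range(y.shape[1])
    ])
    factors = _rescale_geomean(2.0 ** log_f)
    return NormalizationFactors(
        pd.Series(factors, index=counts.sample_ids), "tmm",
        pd.Series(lib, index=counts.sample_ids),
    )


def uq_factors(counts: ExpressionMatrix) -> NormalizationFactors:
    """Upper-quartile scaling factors.

    Per sample, the 75th percentile (linear-interpolation definition) of
    counts over genes with nonzero total across samples, divided by the
    library size; rescaled to geometric mean 1.
    """
    y = _require_counts(counts)
    expressed = y.sum(axis=1) > 0
    if not expressed.any():
        raise ValueError("all genes have zero counts")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample in count matrix")
    uq = np.percentile(y[expressed], 75, axis=0)
    if (uq == 0).any():
        raise ValueError("a sample has zero 75th-percentile count")
    factors = _rescale_geomean(uq / lib)
    return NormalizationFactors(
        pd.Series(factors, index=counts.sample_ids), "uq",
        pd.Series(lib, index=counts.sample_ids),
    )


def cpm(counts: ExpressionMatrix, factors: NormalizationFactors) -> ExpressionMatrix:
    """Counts per million on effective library sizes (no prior count)."""
    y = _require_counts(counts)
    eff = factors.effective_lib_sizes.reindex(counts.sample_ids)
    if eff.isna().any():
        raise ValueError("factors do not cover all samples")
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    vals = y / eff.to_numpy() * 1e6
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids), "cpm"
    )


def log_cpm(
    counts: ExpressionMatrix, factors: NormalizationFactors, prior: float = 0.5
) -> ExpressionMatrix:
    """log2 CPM with a prior count added to each observation.

    value = log2((y + prior) / (N_s · f_s) × 10⁶); with prior 0.5 a zero
    count at effective library size 10⁶ maps to exactly −1.
    """
    y = _require_counts(counts)
    eff = factors.effective_lib_sizes.reindex(counts.sample_ids)
    if eff.isna().any():
        raise ValueError("factors do not cover all samples")
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    vals = np.log2((y + prior) / eff.to_numpy() * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids), "logcpm"
    )


def filter_low_expressed(
    counts: ExpressionMatrix,
    factors: NormalizationFactors,
    cpm_floor: float = 10.0,
    frac: float = 0.5,
) -> list[str]:
    """Ids of genes that are not lowly expressed.

    A gene is removed when strictly more than ``frac`` of samples have CPM
    below ``cpm_floor``; a gene at exactly the boundary is kept.
    """
    c = cpm(counts, factors).values.to_numpy()
    n_low = (c < cpm_floor).sum(axis=1)
    keep = n_low <= frac * c.shape[1]
    return [g for g, k in zip(counts.gene_ids, keep) if k]
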