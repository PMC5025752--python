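"""Module eigengene (ME) and module membership (MM) scores.

The ME of a module in a cancer is the first principal component of the
module genes' expression over that cancer's tumor samples, computed on the
covariance matrix (genes centered, no variance scaling). It summarises the
module's activity per sample. MM is each gene's Pearson correlation with
the ME and measures how much the gene contributes to the component. The
component sign is fixed so that the majority of genes have positive MM
(ties: the lexicographically smallest gene's MM is non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = ["ModuleScores", "module_eigengene", "median_split"]


@dataclass
class ModuleScores:
    """Per-sample eigengene scores and per-gene memberships for one module."""

    module_id: int | str
    cancer_type: str
    me: pd.Series  # indexed by sample, zero mean
    mm: pd.Series  # indexed by gene, in [-1, 1]
    var_explained: float

    def __post_init__(self) -> None:
        if abs(self.me.mean()) > 1e-8 * max(1.0, float(np.abs(self.me).max())):
            raise ValueError("module eigengene must have zero mean")
        if not 0.0 <= self.var_explained <= 1.0 + 1e-12:
            raise ValueError("var_explained must lie in [0, 1]")
        if (self.mm.abs() > 1 + 1e-9).any():
            raise ValueError("module membership must lie in [-1, 1]")


def module_eigengene(
    expr: ExpressionMatrix,
    module_genes=None,
    module_id: int | str = 0,
    cancer_type: str = "",
) -> ModuleScores:
    """First principal component of a module's expression submatrix.

    ``expr`` holds the (logCPM) expression of the relevant tumor samples;
    ``module_genes`` restricts it to the module (default: all genes in
    ``expr``). Genes are centered; the decomposition is of the gene-gene
    covariance, so high-variance genes weigh more. Requires ≥2 genes and
    ≥3 samples and a module with nonzero total variance.
    """
    values = expr.values
    if module_genes is not None:
        genes = [g for g in module_genes if g in values.index]
        values = values.loc[genes]
    if values.shape[0] < 2:
        raise ValueError("a module needs at least two genes present in the matrix")
    if values.shape[1] < 3:
        raise ValueError("eigengene needs at least three samples")
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    if not np.any(xc):
        raise ValueError("zero-variance module")
    # SVD of the centered genes × samples block: scores = s1 * v1
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    me = s[0] * vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))

    me_c = me - me.mean()
    me_sd = me_c.std()
    row_sd = xc.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mm = (xc @ me_c) / (x.shape[1] * row_sd * me_sd)
    mm = np.where(row_sd == 0, 0.0, mm)
    mm = np.clip(mm, -1.0, 1.0)

    # orient: maximize the count of positively-correlated genes;
    # break ties toward non-negative MM of the first (sorted) gene
    n_pos, n_neg = int((mm > 0).sum()), int((mm < 0).sum())
    flip = n_pos < n_neg
    if n_pos == n_neg:
        first = int(np.argsort(values.index.to_numpy().astype(str))[0])
        flip = mm[first] < 0
    if flip:
        me, mm = -me, -mm

    return ModuleScores(
        module_id,
        cancer_type,
        pd.Series(me - me.mean(), index=values.columns, name="me"),
        pd.Series(mm, index=values.index, name="mm"),
        var_explained,
    )


def median_split(me: pd.Series) -> pd.Series:
    """Split samples into 'low'/'high' groups at the median ME score.

    Scores at or below the median go to 'low' — ties at the median are
    deterministic by construction.
    """
    if len(me) < 2:
        raise ValueError("median split needs at least two samples")
    med = float(me.median())
    return pd.Series(np.where(me <= med, "low", "high"), index=me.index, name="me_group")
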