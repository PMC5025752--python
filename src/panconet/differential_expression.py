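"""Differential expression contrasts and the gene–cancer specificity statistic.

Two contrasts drive the pipeline: tumor vs matched/organ normal within one
cancer type (TMM-normalised logCPM, BH-adjusted at FDR ≤ 0.001, fold change
≥ 2), and each cancer's tumors vs every other cancer's tumors on the
combined UQ-normalised matrix (Bonferroni over the whole gene × comparison
family per target cancer, adjusted p ≤ 0.001, fold change ≥ 2). The
specificity of a (gene, cancer) pair counts how many other cancers the gene
is differentially expressed against; genes both DE vs normal and specific
above a threshold seed the cancer-specific subnetworks.

The vs-normal contrast offers a plain Welch t test (unequal variances,
Satterthwaite df) and a moderated mode that shrinks per-gene pooled
variances toward a common prior fitted by moment-matching the distribution
of log sample variances — the classic empirical-Bayes construction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import ExpressionMatrix, SampleTable

__all__ = [
    "welch_t",
    "de_vs_normal",
    "de_vs_other_cancers",
    "specificity_scores",
    "select_specific_genes",
]

MIN_NORMALS = 5


def welch_t(x, y, var_floor: float = 1e-24):
    """Two-sided Welch t test with Satterthwaite degrees of freedom.

    Returns ``(statistic, p)``. Both groups constant and equal gives (0, 1)
    by convention; constant but separated groups use ``var_floor`` in place
    of the zero variances so the statistic is finite with the correct sign.
    Groups need at least two values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        v1 = v2 = var_floor
    n1, n2 = x.size, y.size
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def _welch_rows(a: np.ndarray, b: np.ndarray):
    """Vectorised Welch t over rows (genes); returns (t, p, df)."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    zero = se2 == 0
    t[zero] = 0.0
    df[zero] = n1 + n2 - 2
    p = 2 * stats.t.sf(np.abs(t), df)
    p[zero] = 1.0
    return t, p, df


def _fit_f_dist(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior (d0, s0²) to log sample variances.

    Uses the classic identities for z = log s²: E z = log s0² + ψ(d/2) −
    log(d/2) − ψ(d0/2) + log(d0/2) and Var z = ψ'(d/2) + ψ'(d0/2), with the
    trigamma equation inverted by Newton iteration. Returns (inf, exp(mean
    adjustment)) when the empirical variance of z is no larger than the
    sampling component (complete shrinkage).
    """
    z = np.log(np.maximum(s2, 1e-300))
    e_z = z.mean()
    v_z = z.var(ddof=1)
    d2 = df_resid / 2.0
    target = v_z - special.polygamma(1, d2)
    if target <= 0:
        s0_log = e_z - special.polygamma(0, d2) + np.log(d2)
        return np.inf, float(np.exp(s0_log))
    # invert trigamma(x) = target by Newton on x
    x = 0.5 + 1.0 / target
    for _ in range(50):
        f = special.polygamma(1, x) - target
        fp = special.polygamma(2, x)
        step = f / fp
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2
        if abs(x_new - x) < 1e-10 * max(1.0, x):
            x = x_new
            break
        x = x_new
    d0 = 2.0 * x
    s0_log = e_z - special.polygamma(0, d2) + np.log(d2) + special.polygamma(0, x) - np.log(x)
    return float(d0), float(np.exp(s0_log))


def _moderated_rows(a: np.ndarray, b: np.ndarray):
    """Empirical-Bayes moderated t over rows with pooled variances."""
    n1, n2 = a.shape[1], b.shape[1]
    df_resid = n1 + n2 - 2
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
    d0, s0_2 = _fit_f_dist(s2[s2 > 0], df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    delta = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    t[se == 0] = 0.0
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p[se == 0] = 1.0
    return t, p, np.full(t.shape, df_total)


def de_vs_normal(
    logcpm: ExpressionMatrix,
    sample_table: SampleTable,
    cancer_type: str,
    fc_threshold: float = 2.0,
    fdr: float = 0.001,
    method: str = "welch",
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression for one cancer type.

    ``logcpm`` is the TMM-normalised log2 CPM matrix of that cancer's tumor
    and normal samples (pre-filtered for low expression). Requires at least
    five normal samples. log2 fold change is the difference of group means
    on logCPM, so ``fc_threshold=2`` means |Δ| ≥ 1. p values are
    BH-adjusted across genes.

    Returns a DataFrame indexed by gene with columns log2_fc, statistic,
    p, p_adj, is_de and attrs recording the method.
    """
    if logcpm.unit != "logcpm":
        raise ValueError("de_vs_normal expects a logcpm matrix")
    tumors = [s for s in sample_table.samples(cancer_type, "tumor") if s in logcpm.values.columns]
    normals = [s for s in sample_table.samples(cancer_type, "normal") if s in logcpm.values.columns]
    if len(normals) < MIN_NORMALS:
        raise ValueError(
            f"{cancer_type}: only {len(normals)} normal samples; "
            f"at least {MIN_NORMALS} are required for the vs-normal contrast"
        )
    if len(tumors) < 2:
        raise ValueError(f"{cancer_type}: fewer than two tumor samples")
    a = logcpm.values[tumors].to_numpy()
    b = logcpm.values[normals].to_numpy()
    if method == "welch":
        t, p, _ = _welch_rows(a, b)
    elif method == "moderated":
        t, p, _ = _moderated_rows(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    lfc = a.mean(axis=1) - b.mean(axis=1)
    p_adj = bh_adjust(p)
    is_de = (np.abs(lfc) >= np.log2(fc_threshold)) & (p_adj <= fdr)
    out = pd.DataFrame(
        {"log2_fc": lfc, "statistic": t, "p": p, "p_adj": p_adj, "is_de": is_de},
        index=pd.Index(logcpm.gene_ids, name="gene_id"),
    )
    out.attrs["method"] = method
    out.attrs["cancer_type"] = cancer_type
    return out


def de_vs_other_cancers(
    logcpm_tumors: ExpressionMatrix,
    cancer_labels: pd.Series,
    p_threshold: float = 0.001,
    fc_threshold: float = 2.0,
    high_expressed: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Pairwise cancer-vs-cancer differential expression on tumor samples.

    ``logcpm_tumors`` is the combined UQ-normalised logCPM matrix of all
    tumor samples; ``cancer_labels`` maps sample id → cancer type. Each
    target cancer is Welch-tested against every other cancer per gene, and
    the p values are Bonferroni-corrected over that target's whole family
    (tested genes × other cancers). A (gene, target, other) triple is
    flagged when adjusted p ≤ ``p_threshold`` and the |log2 FC| of group
    means is ≥ log2(``fc_threshold``).

    When ``high_expressed`` maps cancer type → gene ids, a gene is tested
    for a (target, other) pair only if it is high-expressed in both; absent
    genes contribute no flag and do not enter the family.

    Returns a long DataFrame (gene_id, target, other, log2_fc, p, p_adj,
    is_de). Cancers with fewer than two tumor samples are excluded with a
    warning.
    """
    if logcpm_tumors.unit != "logcpm":
        raise ValueError("expected a logcpm matrix")
    labels = cancer_labels.reindex(logcpm_tumors.sample_ids)
    cancers = sorted(labels.dropna().unique())
    groups = {}
    for c in cancers:
        cols = [s for s, lab in labels.items() if lab == c]
        if len(cols) < 2:
            warnings.warn(f"{c}: fewer than two tumor samples, excluded from cross-cancer DE")
            continue
        groups[c] = logcpm_tumors.values[cols].to_numpy()
    cancers = sorted(groups)
    if len(cancers) < 2:
        raise ValueError("need at least two cancers with >=2 tumor samples")

    gene_index = pd.Index(logcpm_tumors.gene_ids)
    masks = {}
    for c in cancers:
        if high_expressed is None:
            masks[c] = np.ones(len(gene_index), dtype=bool)
        else:
            masks[c] = gene_index.isin(high_expressed.get(c, []))

    # one symmetric Welch test per unordered pair, recorded for both orders
    pair_stats: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for i, c1 in enumerate(cancers):
        for c2 in cancers[i + 1:]:
            tested = masks[c1] & masks[c2]
            t = np.full(len(gene_index), np.nan)
            p = np.full(len(gene_index), np.nan)
            lfc = np.full(len(gene_index), np.nan)
            if tested.any():
                tt, pp, _ = _welch_rows(groups[c1][tested], groups[c2][tested])
                t[tested], p[tested] = tt, pp
                lfc[tested] = groups[c1][tested].mean(axis=1) - groups[c2][tested].mean(axis=1)
            pair_stats[(c1, c2)] = (lfc, p, tested)

    records = []
    for target in cancers:
        family = 0
        rows = []
        for other in cancers:
            if other == target:
                continue
            key = (target, other) if (target, other) in pair_stats else (other, target)
            lfc, p, tested = pair_stats[key]
            sign = 1.0 if key == (target, other) else -1.0
            family += int(tested.sum())
            rows.append((other, sign * lfc, p, tested))
        for other, lfc, p, tested in rows:
            p_adj = np.minimum(1.0, p * family)
            flag = tested & (p_adj <= p_threshold) & (np.abs(lfc) >= np.log2(fc_threshold))
            for gi in np.nonzero(tested)[0]:
                records.append(
                    (gene_index[gi], target, other, lfc[gi], p[gi], p_adj[gi], bool(flag[gi]))
                )
    return pd.DataFrame(
        records, columns=["gene_id", "target", "other", "log2_fc", "p", "p_adj", "is_de"]
    )


def specificity_scores(de_flags: pd.DataFrame) -> pd.DataFrame:
    """Count, per (gene, target cancer), the other cancers it is DE against.

    ``de_flags`` is the long table from :func:`de_vs_other_cancers`.
    Returns a DataFrame (gene_id, cancer_type, specificity).
    """
    counts = (
        de_flags.groupby(["gene_id", "target"])["is_de"].sum().astype(int).reset_index()
    )
    return counts.rename(columns={"target": "cancer_type", "is_de": "specificity"})


def select_specific_genes(
    spec_table: pd.DataFrame,
    de_vs_normal_flags: dict[str, pd.DataFrame],
    threshold: int,
) -> dict[str, set[str]]:
    """Cancer-specific gene sets.

    A gene is specific to cancer c when it is DE vs normal in c and its
    specificity count is no less than ``threshold`` ("no less than" —
    equality qualifies). ``de_vs_normal_flags`` maps cancer type → the
    vs-normal result table.
    """
    out: dict[str, set[str]] = {}
    for cancer, de_table in de_vs_normal_flags.items():
        de_genes = set(de_table.index[de_table["is_de"]])
        sub = spec_table[spec_table["cancer_type"] == cancer]
        specific = set(sub.loc[sub["specificity"] >= threshold, "gene_id"])
        max_spec = int(sub["specificity"].max()) if len(sub) else 0
        if not specific and threshold > max_spec:
            warnings.warn(
                f"{cancer}: specificity threshold {threshold} exceeds the maximum "
                f"observed ({max_spec}); empty specific set"
            )
        out[cancer] = de_genes & specific
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    # local import would be circular; BH lives in association_stats but the
    # DE tables need it too — delegate to statsmodels directly here
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
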