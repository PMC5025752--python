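"""The statistical battery linking module eigengene scores to mutations,
copy number, promoter methylation, clinical groups and survival.

Nonparametric two-group comparisons use the two-sided Mann–Whitney U test
(exact by enumeration for small tie-free samples, tie-corrected normal
approximation with continuity correction otherwise); multi-group clinical
comparisons use Kruskal–Wallis. Continuous couplings (SCNA, promoter β)
use Pearson correlation with the exact t-transform p value. Survival is
summarised by Kaplan–Meier curves of the median-split ME groups and
compared with the log-rank test. Gene-set enrichment is the one-sided
hypergeometric (Fisher) tail. Multiple testing within a family is
controlled by Benjamini–Hochberg (or Bonferroni where a family-wise bound
is wanted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = [
    "AssociationResult",
    "SurvivalCurve",
    "mann_whitney_u",
    "mutation_association",
    "pearson_assoc",
    "kruskal_wallis",
    "km_estimator",
    "logrank_test",
    "bh_adjust",
    "bonferroni_adjust",
    "fisher_enrichment",
]

EXACT_MWU_MAX_N = 12


@dataclass
class AssociationResult:
    """One statistical test outcome."""

    test: str  # mwu | kruskal | pearson | logrank | fisher
    target: str
    statistic: float
    p: float
    p_adj: float | None = None
    group_sizes: tuple = ()
    effect: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.p_adj is not None and not 0.0 <= self.p_adj <= 1.0:
            raise ValueError("p_adj must lie in [0, 1]")


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate: S(t) step function with risk sets."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival estimates must be nonincreasing")

    def at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of x, p).

    ``mode='exact'`` enumerates the permutation distribution (valid without
    ties); ``'normal'`` uses the tie-corrected normal approximation with
    continuity correction; ``'auto'`` picks exact when n₁+n₂ ≤ 12 and the
    pooled sample is tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= EXACT_MWU_MAX_N and not has_ties) else "normal"
    if mode == "exact" and has_ties:
        raise ValueError("exact Mann-Whitney mode requires tie-free data")
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u, p = float(res.statistic), float(res.pvalue)
    if mode == "normal" and u == x.size * y.size / 2.0:
        p = 1.0  # dead-centre statistic: symmetric, no evidence either way
    return u, min(p, 1.0)


def mutation_association(
    me: pd.Series, mutation_table: pd.DataFrame, min_group: int = 3
) -> pd.DataFrame:
    """Mann–Whitney tests of ME score by mutation status, per gene.

    ``me`` is indexed by patient id. Genes in ``mutation_table`` (already
    restricted upstream to significantly mutated genes, q < 0.1) with at
    least ``min_group`` patients in both the mutant and wild-type group are
    tested; the rest are recorded as untested. p values are BH-adjusted
    over the tested genes.

    Returns a DataFrame (gene_id, n_mutant, n_wild_type, statistic, p,
    p_adj, tested).
    """
    rows = []
    for gene, sub in mutation_table.groupby("gene_id"):
        status = sub.set_index("patient_id")["status"]
        common = status.index.intersection(me.index)
        mut = me[common[status[common] == "mutant"]]
        wt = me[common[status[common] == "wild_type"]]
        if len(mut) < min_group or len(wt) < min_group:
            rows.append((gene, len(mut), len(wt), np.nan, np.nan, False))
            continue
        u, p = mann_whitney_u(mut.to_numpy(), wt.to_numpy(), mode="normal")
        rows.append((gene, len(mut), len(wt), u, p, True))
    out = pd.DataFrame(rows, columns=["gene_id", "n_mutant", "n_wild_type", "statistic", "p", "tested"])
    out["p_adj"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out[["gene_id", "n_mutant", "n_wild_type", "statistic", "p", "p_adj", "tested"]]


def pearson_assoc(me, values) -> tuple[float, float]:
    """Pearson correlation with the exact two-sided t-transform p value.

    Needs ≥3 paired observations and nonzero variance in both vectors.
    """
    me = np.asarray(me, dtype=float)
    values = np.asarray(values, dtype=float)
    if me.size != values.size:
        raise ValueError("paired vectors must have equal length")
    if me.size < 3:
        raise ValueError("Pearson association needs at least three observations")
    if me.std() == 0 or values.std() == 0:
        raise ValueError("constant input to Pearson association")
    r, p = stats.pearsonr(me, values)
    return float(r), float(p)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p over ≥2 groups.

    All observations identical gives (0, 1) by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("Kruskal-Wallis needs >=2 non-empty groups")
    if sum(g.size for g in groups) < 3:
        raise ValueError("Kruskal-Wallis needs at least three observations")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def km_estimator(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate.

    ``events`` is boolean (False = censored); censored subjects leave the
    risk set after their time. With no censoring the curve equals the
    empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    ts = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(ts).to_numpy(dtype=float)
    keep = np.isin(ts, times)  # drop the synthetic t=0 anchor unless observed
    return SurvivalCurve(ts[keep], at_risk[keep], surv[keep])


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    At each distinct event time, observed events in group 1 are compared
    with their hypergeometric expectation; the squared standardised sum is
    chi-square with 1 df. Exactly two group labels are required and both
    groups must be non-empty.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("log-rank test requires exactly two groups")
    mask = groups == labels[0]
    if mask.all() or not mask.any():
        raise ValueError("both groups must be non-empty")
    res = _lifelines_logrank(
        times[mask], times[~mask], event_observed_A=events[mask], event_observed_B=events[~mask]
    )
    return float(res.test_statistic), float(res.p_value)


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values."""
    p = _check_p(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p) -> np.ndarray:
    """Bonferroni adjustment: min(1, m·p)."""
    p = _check_p(p)
    return np.minimum(1.0, p * p.size)


def fisher_enrichment(
    module_genes, gene_sets: GeneSetCollection, universe, two_sided: bool = False
) -> pd.DataFrame:
    """Over-representation of gene sets in a module by hypergeometric tail.

    ``module_genes`` must lie in ``universe``; each set is intersected with
    the universe first. The default is the one-sided enrichment tail
    P(X ≥ overlap); ``two_sided`` switches to Fisher's two-sided exact
    test. BH correction runs across sets.

    Returns a DataFrame (set_id, overlap, set_size, module_size, p, p_adj)
    sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes)
    if not module <= universe:
        raise ValueError("module genes must be contained in the universe")
    n_univ, n_mod = len(universe), len(module)
    rows = []
    for set_id, (_, members) in gene_sets.items():
        in_univ = set(members) & universe
        k = len(in_univ & module)
        n_set = len(in_univ)
        if n_set == 0:
            continue
        if two_sided:
            other = n_univ - n_set
            table = [[k, n_set - k], [n_mod - k, other - (n_mod - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = float(stats.hypergeom.sf(k - 1, n_univ, n_set, n_mod))
        rows.append((set_id, k, n_set, n_mod, p))
    out = pd.DataFrame(rows, columns=["set_id", "overlap", "set_size", "module_size", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
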