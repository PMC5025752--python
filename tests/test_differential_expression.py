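"""DE contrasts: hand-computed Welch values, planted-effect recovery,
error-rate calibration and the specificity counting statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panconet.differential_expression import (
    de_vs_normal,
    de_vs_other_cancers,
    select_specific_genes,
    specificity_scores,
    welch_t,
)
from panconet.io_formats import ExpressionMatrix, SampleTable


def _logcpm(values, samples=None):
    values = np.asarray(values, dtype=float)
    genes = [f"G{i:04d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "logcpm")


class TestWelch:
    def test_identical_vectors(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0 and p == pytest.approx(1.0)

    def test_separated_constant_groups(self):
        t, p = welch_t([0, 0, 0, 0], [1, 1, 1, 1])
        assert t < 0
        assert p < 1e-6

    def test_hand_computed_example(self):
        # independent direct-formula computation for x=(1,2,3), y=(2,4,6)
        x, y = np.array([1.0, 2, 3]), np.array([2.0, 4, 6])
        v1, v2, n1, n2 = x.var(ddof=1), y.var(ddof=1), 3, 3
        se2 = v1 / n1 + v2 / n2
        t_exp = (x.mean() - y.mean()) / np.sqrt(se2)
        df_exp = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p_exp = 2 * stats.t.sf(abs(t_exp), df_exp)
        t, p = welch_t(x, y)
        assert t == pytest.approx(t_exp, rel=1e-12)
        assert p == pytest.approx(p_exp, rel=1e-12)

    def test_label_swap_negates_statistic(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 2, 10)
        t1, p1 = welch_t(x, y)
        t2, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


def _cohort_table(n_tumor, n_normal, cancer="CA"):
    rows = [(f"T{i}", f"P{i}", cancer, "tumor") for i in range(n_tumor)]
    rows += [(f"N{i}", f"Q{i}", cancer, "normal") for i in range(n_normal)]
    return SampleTable(
        pd.DataFrame(rows, columns=["sample_id", "patient_id", "cancer_type", "tissue_status"])
    )


class TestDeVsNormal:
    @pytest.mark.parametrize("method", ["welch", "moderated"])
    def test_planted_effect_detected(self, method):
        n_seeds, hits = 200, 0
        table = _cohort_table(30, 10)
        cols = table.samples("CA", "tumor") + table.samples("CA", "normal")
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            vals = rng.normal(8.0, 0.5, size=(60, 40))
            vals[0, :30] += 3.0  # planted log2FC on the tumor group
            de = de_vs_normal(_logcpm(vals, cols), table, "CA", method=method)
            hits += bool(de["is_de"].iloc[0])
        assert hits / n_seeds >= 0.99

    def test_null_flag_rate_below_nominal(self):
        # 2000 null genes x 20 reps at FDR 0.001: expect ~0 flags
        table = _cohort_table(30, 10)
        cols = table.samples("CA", "tumor") + table.samples("CA", "normal")
        flags = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            vals = rng.normal(8.0, 0.5, size=(2000, 40))
            de = de_vs_normal(_logcpm(vals, cols), table, "CA")
            flags += int(de["is_de"].sum())
        assert flags / (2000 * 20) <= 0.002

    def test_equal_groups_give_zero_degs(self, rng):
        table = _cohort_table(6, 6)
        base = rng.normal(8, 1, size=(100, 6))
        vals = np.concatenate([base, base], axis=1)
        cols = table.samples("CA", "tumor") + table.samples("CA", "normal")
        de = de_vs_normal(_logcpm(vals, cols), table, "CA")
        assert de["is_de"].sum() == 0

    def test_too_few_normals_refused(self, rng):
        table = _cohort_table(10, 4)
        cols = table.samples("CA", "tumor") + table.samples("CA", "normal")
        with pytest.raises(ValueError, match="at least 5"):
            de_vs_normal(_logcpm(rng.normal(size=(5, 14)), cols), table, "CA")


class TestDeVsOthers:
    def test_bonferroni_family_arithmetic(self):
        # p=0.0001 against a 135000-test family is not significant
        assert min(1.0, 0.0001 * 135000) == 1.0

    def test_identical_cancers_no_flags(self, rng):
        base = rng.normal(8, 0.5, size=(50, 20))
        vals = np.concatenate([base, base], axis=1)
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=[f"S{j}" for j in range(40)])
        res = de_vs_other_cancers(_logcpm(vals), labels)
        assert not res["is_de"].any()

    def test_planted_marker_flagged_against_both_others(self):
        hits = 0
        n_seeds = 100
        labels = pd.Series(
            ["A"] * 40 + ["B"] * 40 + ["C"] * 40, index=[f"S{j}" for j in range(120)]
        )
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            vals = rng.normal(8.0, 0.5, size=(100, 120))
            vals[0, :40] += 4.0  # 16-fold marker in cancer A only
            res = de_vs_other_cancers(_logcpm(vals), labels)
            g0 = res[(res["gene_id"] == "G0000") & (res["target"] == "A")]
            hits += int(g0["is_de"].all() and len(g0) == 2)
        assert hits / n_seeds >= 0.95

    def test_bonferroni_adjustment_exact(self, rng):
        vals = rng.normal(8, 0.5, size=(30, 30))
        labels = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=[f"S{j}" for j in range(30)])
        res = de_vs_other_cancers(_logcpm(vals), labels)
        family = 30 * 2  # genes x other cancers, per target
        np.testing.assert_allclose(
            res["p_adj"].to_numpy(), np.minimum(1.0, res["p"].to_numpy() * family)
        )

    def test_tiny_cancer_excluded_with_warning(self, rng):
        vals = rng.normal(8, 0.5, size=(10, 21))
        labels = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"], index=[f"S{j}" for j in range(21)])
        with pytest.warns(UserWarning, match="fewer than two"):
            res = de_vs_other_cancers(_logcpm(vals), labels)
        assert set(res["target"]) == {"A", "B"}


class TestSpecificity:
    def test_counting_matches_brute_force(self, rng):
        genes = [f"G{i}" for i in range(12)]
        cancers = ["A", "B", "C", "D"]
        rows = []
        for g in genes:
            for t in cancers:
                for o in cancers:
                    if t != o:
                        rows.append((g, t, o, 0.0, 0.5, 1.0, bool(rng.random() < 0.4)))
        flags = pd.DataFrame(
            rows, columns=["gene_id", "target", "other", "log2_fc", "p", "p_adj", "is_de"]
        )
        spec = specificity_scores(flags).set_index(["gene_id", "cancer_type"])["specificity"]
        for g in genes:
            for t in cancers:
                manual = int(
                    flags[(flags.gene_id == g) & (flags.target == t)]["is_de"].sum()
                )
                assert spec[(g, t)] == manual

    def test_threshold_boundary_and_normal_requirement(self):
        spec = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "cancer_type": ["A", "A"], "specificity": [12, 12]}
        )
        de = pd.DataFrame({"is_de": [True, False]}, index=["g1", "g2"])
        out = select_specific_genes(spec, {"A": de}, threshold=12)
        assert out["A"] == {"g1"}  # specificity == threshold qualifies; g2 not DE vs normal

    def test_threshold_zero_gives_all_degs(self):
        spec = pd.DataFrame({"gene_id": ["g1"], "cancer_type": ["A"], "specificity": [0]})
        de = pd.DataFrame({"is_de": [True]}, index=["g1"])
        assert select_specific_genes(spec, {"A": de}, threshold=0)["A"] == {"g1"}

    def test_threshold_above_max_warns_empty(self):
        spec = pd.DataFrame({"gene_id": ["g1"], "cancer_type": ["A"], "specificity": [2]})
        de = pd.DataFrame({"is_de": [True]}, index=["g1"])
        with pytest.warns(UserWarning, match="exceeds the maximum"):
            out = select_specific_genes(spec, {"A": de}, threshold=99)
        assert out["A"] == set()
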