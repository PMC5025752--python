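"""The association battery against enumeration, hand tables and closed forms."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panconet.association_stats import (
    bh_adjust,
    bonferroni_adjust,
    fisher_enrichment,
    km_estimator,
    kruskal_wallis,
    logrank_test,
    mann_whitney_u,
    mutation_association,
    pearson_assoc,
)
from panconet.io_formats import GeneSetCollection


def mwu_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    mean_u = n1 * (len(pooled) - n1) / 2
    dev = abs(u_obs - mean_u)
    return np.mean(np.abs(us - mean_u) >= dev - 1e-12)


class TestMannWhitney:
    def test_textbook_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_sets_symmetric(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="normal")
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_exhaustively(self, rng):
        # every tie-free configuration up to n1+n2 <= 10 drawn at random
        for trial in range(30):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 11 - n1))
            pooled = rng.permutation(np.arange(n1 + n2, dtype=float) + rng.normal(0, 0.01))
            x, y = pooled[:n1], pooled[n1:]
            _, p = mann_whitney_u(x, y, mode="exact")
            assert p == pytest.approx(mwu_exact_oracle(x, y), abs=1e-12)

    def test_normal_mode_close_to_exact(self, rng):
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.8, 1, 6)
        _, p_exact = mann_whitney_u(x, y, mode="exact")
        _, p_norm = mann_whitney_u(x, y, mode="normal")
        assert abs(p_exact - p_norm) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError, match="tie-free"):
            mann_whitney_u([1.0, 1.0], [1.0, 2.0], mode="exact")


class TestMutationAssociation:
    def _table(self, patients, status, gene="DRV"):
        return pd.DataFrame(
            {"patient_id": patients, "gene_id": gene, "status": status, "q_value": 0.001}
        )

    def test_planted_coupling_detected(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            me = pd.Series(rng.normal(size=100), index=[f"P{i}" for i in range(100)])
            p_mut = 1 / (1 + np.exp(-2.0 * me))
            status = np.where(rng.random(100) < p_mut, "mutant", "wild_type")
            res = mutation_association(me, self._table(me.index, status))
            hits += bool(res["p_adj"].iloc[0] < 0.05)
        assert hits / n_seeds >= 0.90

    def test_permuted_labels_uniform_p(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            me = pd.Series(rng.normal(size=60), index=[f"P{i}" for i in range(60)])
            status = rng.permutation(["mutant"] * 20 + ["wild_type"] * 40)
            res = mutation_association(me, self._table(me.index, status))
            ps.append(res["p"].iloc[0])
        stat, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01  # no evidence of non-uniformity under the null

    def test_small_group_skipped(self):
        me = pd.Series(np.arange(10.0), index=[f"P{i}" for i in range(10)])
        status = ["mutant"] * 2 + ["wild_type"] * 8
        res = mutation_association(me, self._table(me.index, status), min_group=3)
        assert not res["tested"].iloc[0]
        assert np.isnan(res["p"].iloc[0])


class TestPearson:
    def test_perfect_linear(self):
        me = np.array([1.0, 2, 3, 4])
        r, _ = pearson_assoc(me, 2 * me + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_assoc(me, -me)
        assert r == pytest.approx(-1.0)

    def test_p_matches_t_transform(self, rng):
        me = rng.normal(size=10)
        vals = me + rng.normal(size=10)
        r, p = pearson_assoc(me, vals)
        t = r * np.sqrt(8 / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 8), abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_assoc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKruskal:
    def test_identical_groups_convention(self):
        h, p = kruskal_wallis([[1.0, 1.0], [1.0], [1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_two_groups_close_to_mwu(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.7, 1, 15)
        _, p_kw = kruskal_wallis([x, y])
        _, p_mwu = mann_whitney_u(x, y, mode="normal")
        assert abs(p_kw - p_mwu) < 0.02

    def test_tie_correction_hand_computation(self):
        groups = [[1.0, 2.0, 2.0], [2.0, 3.0], [3.0, 4.0]]
        # hand computation with midranks and the tie-correction factor
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        idx = 0
        h = 0.0
        for g in groups:
            r = ranks[idx : idx + len(g)]
            idx += len(g)
            h += r.sum() ** 2 / len(g)
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        h /= 1 - np.sum(counts**3 - counts) / (n**3 - n)
        got_h, _ = kruskal_wallis(groups)
        assert got_h == pytest.approx(h, abs=1e-12)


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        curve = km_estimator([1.0, 2.0, 3.0], [True, True, True])
        assert curve.at(1.0) == pytest.approx(2 / 3)
        assert curve.at(2.5) == pytest.approx(1 / 3)
        assert curve.at(3.0) == pytest.approx(0.0)

    def test_all_censored_flat(self):
        curve = km_estimator([5.0, 8.0, 2.0], [False, False, False])
        np.testing.assert_allclose(curve.survival, 1.0)

    def test_mixed_fixture_hand_table(self):
        # 5 subjects: events at 2, 4, 7; censored at 3 and 5
        times = [2.0, 3.0, 4.0, 5.0, 7.0]
        events = [True, False, True, False, True]
        curve = km_estimator(times, events)
        assert curve.at(2.0) == pytest.approx(4 / 5)
        assert curve.at(4.0) == pytest.approx(4 / 5 * 2 / 3)
        assert curve.at(7.0) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=40)
        curve = km_estimator(t, np.ones(40, dtype=bool))
        for q in [2.0, 5.0, 12.0]:
            assert curve.at(q) == pytest.approx(np.mean(t > q))


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        g = np.array(["a", "b"] * 3)
        chi, p = logrank_test(np.concatenate([t, t]), np.ones(12, bool), np.repeat(["a", "b"], 6))
        # identical samples in both groups: statistic 0
        assert chi == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(5, 30)
        e = rng.random(30) < 0.8
        g = np.array(["a"] * 15 + ["b"] * 15)
        chi1, p1 = logrank_test(t, e, g)
        chi2, p2 = logrank_test(t, e, np.where(g == "a", "b", "a"))
        assert chi1 == pytest.approx(chi2)
        assert p1 == pytest.approx(p2)

    def test_power_under_hazard_ratio_three(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t1 = rng.exponential(1.0, 100)
            t2 = rng.exponential(1 / 3, 100)
            cens = rng.uniform(0, 4.5, 200)  # ~20% censoring
            times = np.minimum(np.concatenate([t1, t2]), cens)
            events = np.concatenate([t1, t2]) <= cens
            _, p = logrank_test(times, events, np.repeat(["lo", "hi"], 100))
            hits += p < 0.01
        assert hits / n_seeds >= 0.95

    def test_one_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [True, True], ["a", "a"])


class TestAdjustments:
    def test_bh_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_singleton_and_bonferroni(self):
        assert bh_adjust([0.001])[0] == pytest.approx(0.001)
        assert bonferroni_adjust([0.001])[0] == pytest.approx(0.001)
        np.testing.assert_allclose(bonferroni_adjust([0.001] * 5), [0.005] * 5)

    def test_matches_direct_formulas_on_random_vectors(self, rng):
        p = rng.uniform(size=50)
        # direct step-up formula, independent implementation
        order = np.argsort(p)
        m = len(p)
        stepped = np.minimum(1, p[order] * m / (np.arange(m) + 1))
        expected = np.minimum.accumulate(stepped[::-1])[::-1]
        got = bh_adjust(p)
        np.testing.assert_allclose(got[order], expected, atol=1e-12)
        np.testing.assert_allclose(bonferroni_adjust(p), np.minimum(1, p * m), atol=1e-15)

    def test_monotonicity(self, rng):
        p = rng.uniform(size=20)
        bumped = p.copy()
        bumped[3] = min(1.0, bumped[3] + 0.2)
        assert (bh_adjust(bumped) >= bh_adjust(p) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFisherEnrichment:
    def test_hand_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection({"S": ("desc", universe[:5])})
        res = fisher_enrichment(universe[:4], sets, universe)
        assert res.loc[0, "overlap"] == 4
        assert res.loc[0, "p"] == pytest.approx(5 / 210)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection({"S": ("d", universe[10:13])})
        res = fisher_enrichment(universe[:3], sets, universe)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_null_modules_uniform_p(self, rng):
        universe = [f"g{i}" for i in range(200)]
        sets = GeneSetCollection({f"S{k}": ("d", list(rng.choice(universe, 30, replace=False))) for k in range(5)})
        ps = []
        for _ in range(300):
            module = list(rng.choice(universe, 25, replace=False))
            res = fisher_enrichment(module, sets, universe)
            ps.extend(res["p"])
        # discrete p-values are super-uniform: P(p <= a) <= a under the null
        ps = np.array(ps)
        for a in [0.05, 0.1, 0.25]:
            assert np.mean(ps <= a) <= a + 3 * np.sqrt(a * (1 - a) / len(ps))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment([], GeneSetCollection({"S": ("d", ["a"])}), [])
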