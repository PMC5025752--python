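"""Segment containment, missingness filtering, kNN imputation and
promoter averaging against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from panconet.genomic_mapping import (
    drop_high_missing,
    knn_impute,
    map_probes_to_promoters,
    map_segments_to_genes,
    tumor_minus_normal,
)
from panconet.io_formats import ExpressionMatrix, GeneModel, ProbeAnnotation, SampleTable


def _gene_model(rows):
    return GeneModel(
        pd.DataFrame(
            rows,
            columns=["gene_id", "chromosome", "strand", "tss", "first_exon_end", "gene_start", "gene_end"],
        )
    )


def _segments(rows):
    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "start", "end", "seg_mean"])


class TestSegmentMapping:
    def test_contained_gene_gets_segment_mean(self):
        gm = _gene_model([("g1", "1", "+", 100, 150, 100, 200)])
        seg = _segments([("S1", "1", 50, 500, 0.3)])
        out = map_segments_to_genes(seg, gm)
        assert out.values.loc["g1", "S1"] == pytest.approx(0.3)

    def test_straddling_gene_missing(self):
        gm = _gene_model([("g1", "1", "+", 400, 450, 400, 600)])
        seg = _segments([("S1", "1", 1, 500, 0.3), ("S1", "1", 501, 1000, -0.2)])
        out = map_segments_to_genes(seg, gm)
        assert np.isnan(out.values.loc["g1", "S1"])

    def test_ambiguous_double_containment_missing(self):
        gm = _gene_model([("g1", "1", "+", 100, 150, 100, 200)])
        seg = _segments([("S1", "1", 50, 500, 0.3), ("S1", "1", 90, 300, 0.7)])
        with pytest.warns(UserWarning, match="overlapping"):
            out = map_segments_to_genes(seg, gm)
        assert np.isnan(out.values.loc["g1", "S1"])

    def test_matches_containment_oracle_and_row_order_invariance(self, rng):
        genes = [(f"g{i}", "1", "+", s, s + 10, s, s + 100)
                 for i, s in enumerate(range(1, 5000, 137))]
        gm = _gene_model(genes)
        rows = []
        for s in ["A", "B"]:
            pos = 1
            while pos < 5000:
                length = int(rng.integers(50, 800))
                rows.append((s, "1", pos, pos + length - 1, float(rng.normal())))
                pos += length + int(rng.integers(0, 100))  # occasional gaps
        seg = _segments(rows)
        out = map_segments_to_genes(seg, gm)
        shuffled = map_segments_to_genes(seg.sample(frac=1, random_state=0), gm)
        pd.testing.assert_frame_equal(out.values, shuffled.values)
        for gid, _, _, _, _, gs, ge in genes:
            for s in ["A", "B"]:
                hits = [
                    m for (smp, _, st, en, m) in rows
                    if smp == s and st <= gs and en >= ge
                ]
                got = out.values.loc[gid, s]
                if len(hits) == 1:
                    assert got == pytest.approx(hits[0])
                else:
                    assert np.isnan(got)


class TestMissingFilter:
    def test_strict_boundary(self):
        vals = pd.DataFrame(
            {
                f"S{j}": [np.nan if j < 6 else 1.0, np.nan if j < 5 else 1.0, 1.0]
                for j in range(10)
            },
            index=["removed", "kept", "full"],
        )
        out = drop_high_missing(ExpressionMatrix(vals, "cna"))
        assert list(out.values.index) == ["kept", "full"]

    def test_all_missing_removed_and_identity(self):
        vals = pd.DataFrame({"S1": [np.nan, 1.0], "S2": [np.nan, 2.0]}, index=["gone", "kept"])
        out = drop_high_missing(ExpressionMatrix(vals, "cna"))
        assert list(out.values.index) == ["kept"]
        full = ExpressionMatrix(vals.loc[["kept"]], "cna")
        pd.testing.assert_frame_equal(drop_high_missing(full).values, full.values)


class TestKnnImpute:
    def test_two_neighbor_mean(self):
        vals = pd.DataFrame(
            [[np.nan, 5.0, 5.0], [4.0, 5.0, 5.0], [6.0, 5.0, 5.0]],
            index=["g0", "g1", "g2"],
            columns=["a", "b", "c"],
        )
        out = knn_impute(ExpressionMatrix(vals, "cna"), k=2)
        assert out.values.loc["g0", "a"] == pytest.approx(5.0)

    def test_complete_matrix_unchanged(self, rng):
        vals = pd.DataFrame(rng.normal(size=(12, 5)))
        vals.index = vals.index.map(str)
        vals.columns = vals.columns.map(str)
        m = ExpressionMatrix(vals, "cna")
        pd.testing.assert_frame_equal(knn_impute(m, k=3).values, vals)

    def test_observed_entries_never_altered(self, rng):
        x = rng.normal(size=(30, 8))
        mask = rng.random(x.shape) < 0.1
        xm = np.where(mask, np.nan, x)
        vals = pd.DataFrame(xm, index=[f"g{i}" for i in range(30)], columns=[f"s{j}" for j in range(8)])
        out = knn_impute(ExpressionMatrix(vals, "cna"), k=5)
        np.testing.assert_allclose(out.values.to_numpy()[~mask], x[~mask])
        assert not np.isnan(out.values.to_numpy()).any()

    def test_matches_exhaustive_oracle(self, rng):
        x = rng.normal(size=(50, 10))
        holes = rng.random(x.shape) < 0.05
        xm = np.where(holes, np.nan, x)
        vals = pd.DataFrame(xm, index=[f"g{i:02d}" for i in range(50)], columns=[f"s{j}" for j in range(10)])
        out = knn_impute(ExpressionMatrix(vals, "cna"), k=10).values.to_numpy()
        obs = ~np.isnan(xm)
        for g in range(50):
            for s in range(10):
                if obs[g, s]:
                    continue
                # exhaustive nearest-neighbor search, written independently
                dists = []
                for h in range(50):
                    if h == g:
                        continue
                    both = obs[g] & obs[h]
                    if not both.any():
                        continue
                    d = np.sqrt(((xm[g, both] - xm[h, both]) ** 2).sum() * 10 / both.sum())
                    dists.append((d, h))
                dists.sort()
                chosen = [h for _, h in dists if obs[h, s]][:10]
                assert out[g, s] == pytest.approx(np.mean(xm[chosen, s]), abs=1e-12)


class TestTumorMinusNormal:
    def _table(self, rows):
        return SampleTable(
            pd.DataFrame(rows, columns=["sample_id", "patient_id", "cancer_type", "tissue_status"])
        )

    def test_normals_averaged_then_subtracted(self):
        vals = pd.DataFrame({"t1": [0.8], "n1": [0.1], "n2": [0.3]}, index=["g"])
        st = self._table([("t1", "P1", "C", "tumor"), ("n1", "P1", "C", "normal"), ("n2", "P1", "C", "normal")])
        out = tumor_minus_normal(ExpressionMatrix(vals, "cna"), st)
        assert out.values.loc["g", "P1"] == pytest.approx(0.6)

    def test_exclusions(self):
        vals = pd.DataFrame(
            {"t1": [0.5], "t2": [0.6], "n1": [0.1], "t3": [0.9]}, index=["g"]
        )
        st = self._table(
            [
                ("t1", "P1", "C", "tumor"),
                ("t2", "P1", "C", "tumor"),  # two tumors -> excluded
                ("n1", "P1", "C", "normal"),
                ("t3", "P2", "C", "tumor"),  # no normal -> excluded
            ]
        )
        with pytest.warns(UserWarning, match="excluded"):
            out = tumor_minus_normal(ExpressionMatrix(vals, "cna"), st)
        assert out.values.shape[1] == 0

    def test_identical_tumor_normal_gives_zero(self):
        vals = pd.DataFrame({"t1": [0.4], "n1": [0.4]}, index=["g"])
        st = self._table([("t1", "P1", "C", "tumor"), ("n1", "P1", "C", "normal")])
        out = tumor_minus_normal(ExpressionMatrix(vals, "cna"), st)
        assert out.values.loc["g", "P1"] == pytest.approx(0.0)


class TestPromoterMapping:
    def _ann(self, rows):
        return ProbeAnnotation(pd.DataFrame(rows, columns=["probe_id", "gene_id", "region_tags"]))

    def test_tag_rules(self):
        ann = self._ann(
            [
                ("p_body", "g1", frozenset({"body"})),
                ("p_tss", "g1", frozenset({"TSS200"})),
                ("p_mixed", "g1", frozenset({"body", "TSS200"})),
                ("p_other", "g2", frozenset({"3'UTR"})),
            ]
        )
        beta = ExpressionMatrix(
            pd.DataFrame(
                {"s1": [0.9, 0.2, 0.4, 0.5]}, index=["p_body", "p_tss", "p_mixed", "p_other"]
            ),
            "beta",
        )
        out = map_probes_to_promoters(beta, ann)
        # body-only probe excluded, any-of rule includes the mixed probe
        assert out.values.loc["g1", "s1"] == pytest.approx((0.2 + 0.4) / 2)
        assert "g2" not in out.values.index  # no promoter probe

    def test_commutes_with_sample_subsetting(self, rng):
        probes = [(f"p{i}", f"g{i//2}", frozenset({"TSS1500"})) for i in range(8)]
        ann = self._ann(probes)
        vals = pd.DataFrame(
            rng.uniform(0, 1, size=(8, 6)),
            index=[p for p, _, _ in probes],
            columns=[f"s{j}" for j in range(6)],
        )
        beta = ExpressionMatrix(vals, "beta")
        full = map_probes_to_promoters(beta, ann)
        sub = map_probes_to_promoters(ExpressionMatrix(vals[["s1", "s4"]], "beta"), ann)
        pd.testing.assert_frame_equal(full.values[["s1", "s4"]], sub.values)
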