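"""TMM normalization, DE rule, gene assignment and contribution summaries."""

import numpy as np
import pandas as pd
import pytest

from enhancerkit.expression import (
    assign_enhancers_to_genes,
    call_de_genes,
    contribution_summary,
    map_nearest_genes_rose,
    nearest_rank_correlation,
    tmm_cpm,
    tmm_factors,
    tpm,
)
from enhancerkit.intervals import GeneModel, IntervalSet


def make_gene(gene_id, chrom, tss, strand="+"):
    exons = IntervalSet(pd.DataFrame(
        {"chrom": [chrom], "start": [tss], "end": [tss + 1000]}))
    return GeneModel(gene_id, chrom, strand, tss, exons)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, size=150)
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        np.testing.assert_allclose(tmm_factors(counts), 1.0, atol=1e-12)

    def test_pure_depth_change_gives_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(200, size=300) + 1
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        np.testing.assert_allclose(tmm_factors(counts), 1.0, atol=1e-9)

    def test_matches_edger_on_frozen_matrix(self):
        # expected factors computed once with Bioconductor
        # edgeR::calcNormFactors on this exact seeded matrix
        rng = np.random.default_rng(42)
        base = rng.lognormal(5, 1.2, size=200)
        c1 = rng.poisson(base)
        c2 = rng.poisson(base * 2.0)
        c3 = rng.poisson(base).astype(float)
        c3[:20] *= 8
        counts = pd.DataFrame({"s1": c1, "s2": c2, "s3": c3.astype(int)})
        np.testing.assert_allclose(
            tmm_factors(counts),
            [1.1527260300, 1.1542616303, 0.7515703537],
            atol=1e-9,
        )

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(80, size=(200, 3)) + 1,
                              columns=list("abc"))
        perm = counts.sample(frac=1, random_state=0)
        np.testing.assert_allclose(
            tmm_factors(counts), tmm_factors(perm), atol=1e-12)

    def test_all_zero_column_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="zero total"):
            tmm_factors(counts)

    def test_cpm_uses_effective_library(self):
        counts = pd.DataFrame({"a": [100, 900], "b": [100, 900]})
        au = tmm_cpm(counts)
        np.testing.assert_allclose(au["a"], [1e5, 9e5])


class TestTpm:
    def test_single_gene(self):
        assert tpm(pd.Series([7]), [500]).iloc[0] == pytest.approx(1e6)

    def test_length_normalization_ratio(self):
        out = tpm(pd.Series([10, 10]), [1000, 2000])
        assert out.iloc[0] / out.iloc[1] == pytest.approx(2.0)
        np.testing.assert_allclose(out, [666666.666667, 333333.333333], rtol=1e-9)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(50, size=(40, 3)) + 1,
                              columns=list("abc"))
        lengths = rng.integers(200, 5000, size=40)
        out = tpm(counts, lengths)
        np.testing.assert_allclose(out.sum(axis=0), 1e6, rtol=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tpm(pd.Series([0, 0]), [100, 100])


class TestDeRule:
    def _expr(self, ctrl, trt):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(ctrl))],
            "au_ctrl": ctrl, "au_trt": trt,
        })

    def test_coverage_and_fold_rules(self):
        expr = call_de_genes(self._expr(
            [9.0, 20.0, 100.0, 5.0, 30.0],
            [9.0, 32.0, 110.0, 12.0, 20.0]))
        # low coverage both; DE up; fc too small; DE up (covered via treated);
        # down at exactly 1.5 -> "no less than 1.5" counts
        assert expr["de"].tolist() == [False, True, False, True, True]
        assert expr["direction"].tolist() == ["none", "up", "none", "up", "down"]


class TestWindowAssignment:
    def test_250kb_rule(self):
        enh = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100_000], "end": [102_000]})
        genes = [
            make_gene("near", "chr1", 300_000),
            make_gene("far", "chr1", 400_000),
            make_gene("inside", "chr1", 101_000),
            make_gene("other_chrom", "chr2", 300_000),
        ]
        links = assign_enhancers_to_genes(enh, genes, window=250_000)
        assert set(links["gene_id"]) == {"near", "inside"}
        by_gene = links.set_index("gene_id")
        assert by_gene.loc["near", "distance"] == 198_001
        assert by_gene.loc["inside", "distance"] == 0


class TestRoseMapping:
    def _expr(self, values):
        return pd.DataFrame({
            "gene_id": list(values),
            "au_ctrl": [v for v in values.values()],
            "au_trt": [v for v in values.values()],
            "log2fc": 0.0,
        })

    def test_nearest_expressed_gene_with_floor(self):
        ses = pd.DataFrame({"chrom": ["chr1"], "start": [99_000], "end": [101_000]})
        tes = pd.DataFrame(columns=["chrom", "start", "end"])
        genes = [make_gene("dim", "chr1", 120_000),      # 20 kb, below floor
                 make_gene("bright", "chr1", 145_000)]   # 45 kb, expressed
        expr = self._expr({"dim": 80.0, "bright": 500.0})
        links = map_nearest_genes_rose(ses, tes, genes, expr)
        se_links = links[links["link_type"] == "nearest_50kb_SE"]
        assert se_links["gene_id"].tolist() == ["bright"]
        assert se_links["distance"].iloc[0] == 45_000

    def test_se_priority_over_te(self):
        ses = pd.DataFrame({"chrom": ["chr1"], "start": [99_000], "end": [101_000]})
        tes = pd.DataFrame({"chrom": ["chr1"], "start": [129_000], "end": [131_000]})
        genes = [make_gene("shared", "chr1", 115_000)]
        expr = self._expr({"shared": 400.0})
        links = map_nearest_genes_rose(ses, tes, genes, expr)
        assert links.loc[links["gene_id"] == "shared", "link_type"].tolist() == [
            "nearest_50kb_SE"]

    def test_unmapped_expressed_genes_are_no_enhancer(self):
        ses = pd.DataFrame(columns=["chrom", "start", "end"])
        tes = pd.DataFrame(columns=["chrom", "start", "end"])
        genes = [make_gene("lonely", "chr1", 1_000_000)]
        expr = self._expr({"lonely": 300.0})
        links = map_nearest_genes_rose(ses, tes, genes, expr)
        assert links["link_type"].tolist() == ["no_enhancer"]

    def test_distance_tie_breaks_to_lower_gene_id(self):
        ses = pd.DataFrame({"chrom": ["chr1"], "start": [99_000], "end": [101_000]})
        tes = pd.DataFrame(columns=["chrom", "start", "end"])
        genes = [make_gene("b_gene", "chr1", 110_000),
                 make_gene("a_gene", "chr1", 90_000)]
        expr = self._expr({"b_gene": 400.0, "a_gene": 400.0})
        links = map_nearest_genes_rose(ses, tes, genes, expr)
        se_links = links[links["link_type"] == "nearest_50kb_SE"]
        assert se_links["gene_id"].tolist() == ["a_gene"]


class TestContribution:
    def _fixture(self):
        # mirrors the published stacked-bar structure: SE-gene totals rise
        # 400 -> 500 A.U. (a 25% increase) and gained-SE genes contribute
        # 84 of the +100 (21 percentage points)
        expr = pd.DataFrame({
            "gene_id": ["g_gain1", "g_gain2", "g_lost", "g_unch"],
            "au_ctrl": [60.0, 40.0, 150.0, 150.0],
            "au_trt": [120.0, 64.0, 140.0, 176.0],
        })
        links = pd.DataFrame({
            "region_idx": [0, 1, 2, 3],
            "chrom": "chr1", "start": 0, "end": 1,
            "gene_id": ["g_gain1", "g_gain2", "g_lost", "g_unch"],
            "distance": 0,
            "link_type": "nearest_50kb_SE",
        })
        se_classes = pd.Series(["gained", "gained", "lost", "unchanged"])
        return links, expr, se_classes

    def test_published_structure_arithmetic(self):
        links, expr, se_classes = self._fixture()
        out = contribution_summary(links, expr, se_classes)
        assert out["percent_change"] == pytest.approx(25.0)
        assert out["class_contributions"]["gained"] == pytest.approx(21.0)
        total = sum(out["class_contributions"].values())
        assert total == pytest.approx(out["percent_change"], abs=1e-12)

    def test_no_change_gives_zero(self):
        links, expr, se_classes = self._fixture()
        expr["au_trt"] = expr["au_ctrl"]
        out = contribution_summary(links, expr, se_classes)
        assert out["percent_change"] == 0.0
        assert all(v == 0.0 for v in out["class_contributions"].values())

    def test_single_class_carries_all(self):
        links, expr, se_classes = self._fixture()
        se_classes[:] = "gained"
        out = contribution_summary(links, expr, se_classes)
        assert out["class_contributions"]["gained"] == pytest.approx(
            out["percent_change"])

    def test_zero_control_total_rejected(self):
        links, expr, se_classes = self._fixture()
        expr["au_ctrl"] = 0.0
        with pytest.raises(ValueError):
            contribution_summary(links, expr, se_classes)


class TestNearestRankCorrelation:
    def _build(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        regions, genes, expr_rows = [], [], []
        for i in range(n):
            base = 1_000_000 * (i + 1)
            sig = float(rng.normal(0, 1))
            regions.append({"chrom": "chr1", "start": base, "end": base + 2000,
                            "signal_log2fc": sig})
            center = base + 1000
            for rank, dist in enumerate([1000, 5000, 9000], start=1):
                gid = f"g{i}_{rank}"
                genes.append(make_gene(gid, "chr1", center + dist))
                expr_rows.append({"gene_id": gid, "log2fc": np.nan, "rank": rank,
                                  "region": i, "sig": sig})
        expr = pd.DataFrame(expr_rows)
        # rank 1 mirrors the region change, rank 2 is permuted noise,
        # rank 3 is anti-correlated
        expr.loc[expr["rank"] == 1, "log2fc"] = expr.loc[expr["rank"] == 1, "sig"]
        perm = rng.permutation(expr.loc[expr["rank"] == 2, "sig"].to_numpy())
        expr.loc[expr["rank"] == 2, "log2fc"] = perm
        expr.loc[expr["rank"] == 3, "log2fc"] = -expr.loc[expr["rank"] == 3, "sig"]
        return pd.DataFrame(regions), genes, expr[["gene_id", "log2fc"]]

    def test_planted_rank_structure(self):
        regions, genes, expr = self._build()
        out = nearest_rank_correlation(regions, genes, expr).set_index("rank")
        assert out.loc[1, "spearman_rho"] == pytest.approx(1.0)
        assert abs(out.loc[2, "spearman_rho"]) < 0.2
        assert out.loc[3, "spearman_rho"] == pytest.approx(-1.0)

    def test_too_few_points_gives_missing(self):
        regions, genes, expr = self._build(n=2)
        out = nearest_rank_correlation(regions, genes, expr).set_index("rank")
        assert np.isnan(out["spearman_rho"]).all()
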