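"""Enhancer calling, enrichment scoring, normalization and moderated testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from enhancerkit.enhancers import (
    EBayesParams,
    bh_adjust,
    call_candidate_enhancers,
    classify_de_novo,
    classify_differential,
    compute_enrichment,
    filter_regulatory,
    moderated_two_group_test,
    quantile_normalize,
)
from enhancerkit.intervals import GeneModel, IntervalSet, SampleTrack


def iset(rows):
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestCandidateCalling:
    def _peaks(self):
        # H3K27ac: region A supported by samples 1+2; region B by sample 1 only;
        # region C supported by 3 samples
        ac = [
            iset([("chr1", 0, 1000), ("chr1", 50_000, 51_000),
                  ("chr1", 100_000, 101_000)]),
            iset([("chr1", 100, 900), ("chr1", 100_200, 101_200)]),
            iset([("chr1", 100_100, 100_800)]),
            iset([]),
        ]
        # H3K4me1: covers regions A and B (2 samples each), nothing at C
        me1 = [
            iset([("chr1", 0, 1200), ("chr1", 49_500, 51_500)]),
            iset([("chr1", 200, 800), ("chr1", 50_100, 50_200)]),
            iset([]),
            iset([]),
        ]
        return ac, me1

    def test_support_and_cooccupancy_rules(self):
        ac, me1 = self._peaks()
        regions, support = call_candidate_enhancers(ac, me1, min_support=2)
        # A retained (ac support 2, me1 support 2); B excluded (ac support 1);
        # C excluded (ac support 3 but no me1 anywhere)
        assert [tuple(r) for r in
                regions.df.itertuples(index=False, name=None)] == [
            ("chr1", 0, 1000)]
        assert support.tolist() == [2]

    def test_mismatched_sample_counts(self):
        ac, me1 = self._peaks()
        with pytest.raises(ValueError, match="mismatch"):
            call_candidate_enhancers(ac[:3], me1)


class TestRegulatoryFilter:
    def test_exclusion_zones(self):
        exons = iset([("chr1", 200_000, 201_000)])
        genes = [GeneModel("g1", "chr1", "+", 100_000, exons
                           if False else iset([("chr1", 100_000, 100_500),
                                               ("chr1", 200_000, 201_000)]))]
        candidates = iset([
            ("chr1", 99_400, 99_600),    # overlaps TSS-1000 window
            ("chr1", 200_999, 202_000),  # overlaps exon by 1 bp
            ("chr1", 300_000, 301_000),  # overlaps H3K4me3 peak
            ("chr1", 400_000, 401_000),  # clean -> retained
        ])
        k4me3 = iset([("chr1", 300_500, 300_600)])
        catalog = filter_regulatory(candidates, genes, k4me3)
        assert [tuple(r)[:3] for r in
                catalog.enhancers.df.itertuples(index=False, name=None)] == [
            ("chr1", 400_000, 401_000)]
        assert catalog.n_removed_promoter == 1
        assert catalog.n_removed_exon == 1
        assert catalog.n_removed_k4me3 == 1


class TestEnrichment:
    def _tracks(self, n_chip, n_input, lib=2_000_000):
        region = ("chr1", 1000, 2000)
        chip = SampleTrack(
            "chip_ctrl_r1", "H3K27ac", "control", 1,
            fragments=iset([("chr1", 1100, 1300)] * n_chip), library_size=lib)
        inp = SampleTrack(
            "input_ctrl", "input", "control", 1,
            fragments=iset([("chr1", 1100, 1300)] * n_input), library_size=lib)
        return iset([region]), [chip], [inp]

    def test_formula(self):
        regions, chip, inp = self._tracks(50, 20)  # scaled 25 and 10
        mat = compute_enrichment(regions, chip, inp)
        assert mat.E.iloc[0, 0] == pytest.approx(np.log2(26 / 11), abs=1e-12)
        assert mat.E.iloc[0, 0] == pytest.approx(1.2410, abs=5e-5)

    def test_identity_and_pseudocount_floor(self):
        regions, chip, inp = self._tracks(30, 30)
        assert compute_enrichment(regions, chip, inp).E.iloc[0, 0] == 0.0
        regions, chip, inp = self._tracks(0, 0)
        chip[0].fragments = iset([("chr2", 0, 10)])
        inp[0].fragments = iset([("chr2", 0, 10)])
        assert compute_enrichment(regions, chip, inp).E.iloc[0, 0] == 0.0

    def test_missing_input_pairing(self):
        regions, chip, inp = self._tracks(10, 10)
        with pytest.raises(ValueError, match="pairing"):
            compute_enrichment(regions, chip, inp, pairing={"other": "x"})


class TestQuantileNormalize:
    def test_hand_computed_2x2(self):
        m = pd.DataFrame([[1.0, 4.0], [3.0, 2.0]], columns=["a", "b"])
        out = quantile_normalize(m)
        assert out.to_numpy().tolist() == [[1.5, 3.5], [3.5, 1.5]]

    def test_identical_columns_fixed_point(self):
        col = np.array([3.0, 1.0, 2.0, 5.0])
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.array_equal(quantile_normalize(m).to_numpy(), m.to_numpy())

    def test_output_distributions_identical_and_idempotent(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        out = quantile_normalize(m)
        ref = np.sort(out.to_numpy()[:, 0])
        for j in range(1, 4):
            assert np.array_equal(np.sort(out.to_numpy()[:, j]), ref)
        again = quantile_normalize(out)
        assert np.array_equal(out.to_numpy(), again.to_numpy())

    def test_ties_get_mean_of_reference_values(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 9.0]})
        out = quantile_normalize(m)
        # column a has a tie on 1.0 -> both get the mean of ranks 1,2 refs
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx(
            (ref[0] + ref[1]) / 2)

    def test_single_column_warns(self):
        m = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        assert out.equals(m)


CONDS = ["control", "control", "treated", "treated"]


class TestModeratedT:
    def test_equal_group_means_give_zero_t(self):
        m = pd.DataFrame([[1.0, 3.0, 2.0, 2.0]], columns=list("abcd"))
        res = moderated_two_group_test(
            m, CONDS, EBayesParams(d0=0.0, s0_sq=1.0, d=2.0))
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_d0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        res = moderated_two_group_test(
            m, CONDS, EBayesParams(d0=0.0, s0_sq=1.0, d=2.0))
        ref = stats.ttest_ind(m.iloc[:, 2:], m.iloc[:, :2], axis=1)
        np.testing.assert_allclose(res["t"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p"], ref.pvalue, atol=1e-10)

    def test_d0_infinite_shares_variance(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        res = moderated_two_group_test(
            m, CONDS, EBayesParams(d0=np.inf, s0_sq=0.25, d=2.0))
        expected = res["logFC"] / np.sqrt(0.25 * (0.5 + 0.5))
        np.testing.assert_allclose(res["t"], expected, atol=1e-12)

    def test_identical_variances_drive_estimate_to_pooled_limit(self):
        # all features share one true variance: the moment estimate of d0 is
        # large and the moderated t approaches the ordinary pooled t
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(scale=1.0, size=(3000, 4)),
                         columns=list("abcd"))
        res = moderated_two_group_test(m, CONDS, "estimate")
        eb = res.attrs["ebayes"]
        assert eb.d0 > 5.0
        assert eb.s0_sq == pytest.approx(1.0, rel=0.2)

    def test_matches_limma_on_frozen_matrix(self):
        # expected values computed once with Bioconductor limma
        # (lmFit + eBayes) on this exact seeded matrix
        rng = np.random.default_rng(42)
        base = rng.lognormal(5, 1.2, size=200)
        for mult in (1.0, 2.0, 1.0):  # stream position matches the generator
            rng.poisson(base * mult)
        E = pd.DataFrame(rng.normal(2.0, 1.0, size=(80, 4)),
                         columns=["c1", "c2", "t1", "t2"])
        E.iloc[:10, 2:] += 2.0
        res = moderated_two_group_test(E, CONDS, "estimate")
        eb = res.attrs["ebayes"]
        assert eb.d0 == pytest.approx(6.4532750025, abs=1e-8)
        assert eb.s0_sq == pytest.approx(0.8853038250, abs=1e-8)
        idx = [0, 1, 4, 10, 39, 79]
        np.testing.assert_allclose(
            res["t"].iloc[idx],
            [0.5770183624, 0.5065314267, 1.5887382790, -0.1041337612,
             -0.1413774510, 0.5922445597],
            atol=1e-8,
        )
        np.testing.assert_allclose(
            res["p"].iloc[idx],
            [5.7896644566e-01, 6.2542941100e-01, 1.4875875856e-01,
             9.1949174571e-01, 8.9088326416e-01, 5.6918621733e-01],
            atol=1e-8,
        )

    def test_zero_variance_feature_with_d0_zero_is_missing(self):
        m = pd.DataFrame(
            [[1.0, 1.0, 3.0, 3.0], [1.0, 2.0, 3.0, 4.0]], columns=list("abcd"))
        res = moderated_two_group_test(
            m, CONDS, EBayesParams(d0=0.0, s0_sq=1.0, d=2.0))
        assert np.isnan(res["t"].iloc[0])
        q = bh_adjust(res["p"].to_numpy())
        assert np.isnan(q[0]) and not np.isnan(q[1])
        labelled = classify_differential(res)
        assert labelled["class"].iloc[0] == "other"


class TestBhAdjust:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_trivial_cases(self):
        assert bh_adjust([0.2]).tolist() == [0.2]
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_monotone_in_p_and_bounded(self, p):
        q = bh_adjust(p)
        assert ((q >= np.asarray(p) - 1e-12) & (q <= 1.0)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestClassification:
    def _table(self, logfc, q, ctrl=1.0, trt=1.0):
        return pd.DataFrame({
            "logFC": [logfc], "t": [1.0], "p": [q], "q": [q],
            "mean_ctrl_E": [ctrl], "mean_trt_E": [trt]})

    @pytest.mark.parametrize(
        "logfc, q, expected",
        [
            (1.2, 0.01, "up"),
            (-1.2, 0.01, "down"),
            (0.05, 0.9, "unaffected_background"),
            (0.5, 0.01, "other"),
            (1.2, 0.2, "other"),
        ],
    )
    def test_differential_classes(self, logfc, q, expected):
        out = classify_differential(self._table(logfc, q))
        assert out["class"].iloc[0] == expected

    @pytest.mark.parametrize(
        "cls, ctrl, trt, expected",
        [
            ("up", 1.0, 1.6, "de_novo_gained"),
            ("up", 1.3, 1.6, "up"),          # control not low enough
            ("down", 1.6, 1.0, "de_novo_lost"),
            ("down", 1.6, 1.2, "down"),      # treated not low enough
            ("unaffected_background", 1.0, 1.6, "unaffected_background"),
        ],
    )
    def test_de_novo_refinement(self, cls, ctrl, trt, expected):
        table = self._table(1.2, 0.01, ctrl, trt)
        table["class"] = [cls]
        out = classify_de_novo(table)
        assert out["class"].iloc[0] == expected

    def test_linear_scale_switch(self):
        # log2 E of 0.8 is linear 1.74 > 1.5: de novo only on the linear scale
        table = self._table(1.2, 0.01, ctrl=0.05, trt=0.8)
        table["class"] = ["up"]
        assert classify_de_novo(table, scale="log2")["class"].iloc[0] == "up"
        assert (
            classify_de_novo(table, scale="linear")["class"].iloc[0]
            == "de_novo_gained"
        )

    def test_swapping_conditions_negates_logfc_and_mirrors_classes(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        m.iloc[:40, 2:] += 2.5
        m.iloc[40:80, 2:] -= 2.5
        fwd = classify_differential(moderated_two_group_test(m, CONDS))
        swapped = ["treated", "treated", "control", "control"]
        rev = classify_differential(moderated_two_group_test(m, swapped))
        np.testing.assert_allclose(rev["logFC"], -fwd["logFC"], atol=1e-12)
        counts_f = fwd["class"].value_counts()
        counts_r = rev["class"].value_counts()
        assert counts_f.get("up", 0) == counts_r.get("down", 0)
        assert counts_f.get("down", 0) == counts_r.get("up", 0)
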