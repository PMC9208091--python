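import numpy as np
import pandas as pd
import pytest

from heteroseq import (
    CountMatrix,
    HeteroseqError,
    SampleDesign,
    bh_adjust,
    call_degs,
    de_test,
    estimate_dispersion,
    estimate_size_factors,
    normalize,
)


def cm(arr, samples):
    arr = np.asarray(arr)
    return CountMatrix(
        pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=samples)
    )


def brute_force_size_factors(arr):
    """Independent median-of-ratios: per sample, median of count/geomean."""
    arr = np.asarray(arr, dtype=float)
    keep = (arr > 0).all(axis=1)
    geo = np.exp(np.mean(np.log(arr[keep]), axis=1))
    return [float(np.median(arr[keep, j] / geo)) for j in range(arr.shape[1])]


def two_group_design(n=3):
    return [SampleDesign(f"a{i}", "P1", i + 1) for i in range(n)] + [
        SampleDesign(f"b{i}", "P2", i + 1) for i in range(n)
    ]


class TestSizeFactors:
    def test_doubled_sample_closed_form(self):
        a = np.array([[10], [20], [30]])
        m = cm(np.hstack([a, 2 * a]), ["A", "B"])
        sf = estimate_size_factors(m)
        assert sf["A"] == pytest.approx(1 / np.sqrt(2))
        assert sf["B"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_give_unit_factors(self):
        a = np.array([[10], [20], [30]])
        m = cm(np.hstack([a, a, a]), ["A", "B", "C"])
        assert estimate_size_factors(m).to_numpy() == pytest.approx([1, 1, 1])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        arr = rng.integers(1, 200, size=(5, 3))
        m = cm(arr, ["s1", "s2", "s3"])
        assert estimate_size_factors(m).to_numpy() == pytest.approx(brute_force_size_factors(arr))

    def test_scale_equivariance_of_factor_ratios(self):
        # scaling one sample's column by c also rescales the geometric-mean
        # reference, so the invariant lives on factor ratios between samples
        rng = np.random.default_rng(0)
        arr = rng.integers(1, 100, size=(20, 3))
        base = estimate_size_factors(cm(arr, ["a", "b", "c"]))
        scaled_arr = arr.copy()
        scaled_arr[:, 1] *= 3
        scaled = estimate_size_factors(cm(scaled_arr, ["a", "b", "c"]))
        assert (scaled["b"] / scaled["a"]) / (base["b"] / base["a"]) == pytest.approx(3.0, rel=1e-9)
        assert (scaled["c"] / scaled["a"]) == pytest.approx(base["c"] / base["a"], rel=1e-9)

    def test_all_zero_genes_rejected(self):
        m = cm([[0, 5], [3, 0]], ["a", "b"])
        with pytest.raises(HeteroseqError, match="nonzero"):
            estimate_size_factors(m)


class TestNormalize:
    def test_unit_factors_identity(self):
        m = cm([[1, 2], [3, 4]], ["a", "b"])
        sf = pd.Series([1.0, 1.0], index=["a", "b"])
        assert normalize(m, sf).equals(m.df.astype(float))

    def test_doubling_counts_and_factor_invariant(self):
        m1 = cm([[10, 4], [6, 8]], ["a", "b"])
        m2 = cm([[10, 8], [6, 16]], ["a", "b"])
        sf1 = pd.Series([1.0, 1.0], index=["a", "b"])
        sf2 = pd.Series([1.0, 2.0], index=["a", "b"])
        assert normalize(m1, sf1)["b"].tolist() == normalize(m2, sf2)["b"].tolist()

    def test_column_sums_match_oracle(self):
        rng = np.random.default_rng(7)
        arr = rng.integers(1, 500, size=(8, 3))
        m = cm(arr, ["a", "b", "c"])
        sf = pd.Series(brute_force_size_factors(arr), index=["a", "b", "c"])
        norm = normalize(m, sf)
        expect = arr.sum(axis=0) / sf.to_numpy()
        assert norm.sum(axis=0).to_numpy() == pytest.approx(expect)


class TestDispersion:
    def test_no_variance_floored(self):
        df = pd.DataFrame(
            {"a0": [10.0], "a1": [10.0], "a2": [10.0], "b0": [10.0], "b1": [10.0], "b2": [10.0]},
            index=["g0"],
        )
        disp = estimate_dispersion(df, two_group_design())
        assert disp["g0"] == pytest.approx(1e-8)

    def test_nb_gene_recovered_at_200_replicates(self):
        rng = np.random.default_rng(123)
        alpha, mean, n = 0.1, 200.0, 200
        r = 1 / alpha
        counts = rng.negative_binomial(r, r / (r + mean), size=2 * n).astype(float)
        design = [SampleDesign(f"a{i}", "P1", i + 1) for i in range(n)] + [
            SampleDesign(f"b{i}", "P2", i + 1) for i in range(n)
        ]
        df = pd.DataFrame([counts], index=["g0"], columns=[d.sample_id for d in design])
        disp = estimate_dispersion(df, design)
        assert 0.05 <= disp["g0"] <= 0.2

    def test_single_replicate_everywhere_rejected(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g0"])
        design = [SampleDesign("a", "P1", 1), SampleDesign("b", "P2", 1)]
        with pytest.raises(HeteroseqError, match="replicates"):
            estimate_dispersion(df, design)


class TestDeTest:
    def make_norm(self, a_vals, b_vals):
        design = two_group_design()
        df = pd.DataFrame([list(a_vals) + list(b_vals)], index=["g0"],
                          columns=[d.sample_id for d in design])
        return df, design

    def test_equal_means_give_p_one(self):
        df, design = self.make_norm([10, 10, 10], [10, 10, 10])
        disp = pd.Series([1e-8], index=["g0"])
        res = de_test(df, design, ("P1", "P2"), disp)
        assert res["log2fc"].iloc[0] == 0
        assert res["pvalue"].iloc[0] == 1.0

    def test_all_zero_gene_degenerate(self):
        df, design = self.make_norm([0, 0, 0], [0, 0, 0])
        disp = pd.Series([1e-8], index=["g0"])
        res = call_degs(de_test(df, design, ("P1", "P2"), disp))
        assert res["log2fc"].iloc[0] == 0
        assert res["pvalue"].iloc[0] == 1.0
        assert not res["is_deg"].iloc[0]

    def test_contrast_swap_negates_log2fc(self):
        df, design = self.make_norm([10, 12, 14], [40, 44, 36])
        disp = pd.Series([0.05], index=["g0"])
        fwd = de_test(df, design, ("P1", "P2"), disp)
        rev = de_test(df, design, ("P2", "P1"), disp)
        assert fwd["log2fc"].iloc[0] == pytest.approx(-rev["log2fc"].iloc[0])
        assert fwd["pvalue"].iloc[0] == pytest.approx(rev["pvalue"].iloc[0])

    def test_unknown_genotype_rejected(self):
        df, design = self.make_norm([1, 2, 3], [4, 5, 6])
        disp = pd.Series([0.05], index=["g0"])
        with pytest.raises(HeteroseqError, match="F1a"):
            de_test(df, design, ("F1a", "P1"), disp)

    def test_null_type_one_error_in_liberal_band(self):
        # 5000 null genes, NB(alpha=0.05), 3 vs 3: small-n Wald is slightly
        # miscalibrated but must stay near nominal
        rng = np.random.default_rng(2024)
        n_genes, alpha, mean = 5000, 0.05, 100.0
        r = 1 / alpha
        arr = rng.negative_binomial(r, r / (r + mean), size=(n_genes, 6)).astype(float)
        design = two_group_design()
        df = pd.DataFrame(arr, index=[f"g{i}" for i in range(n_genes)],
                          columns=[d.sample_id for d in design])
        disp = estimate_dispersion(df, design)
        res = de_test(df, design, ("P1", "P2"), disp)
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_power_on_large_effects(self):
        # true 4-fold genes at decent expression are nearly always caught
        rng = np.random.default_rng(99)
        n_genes, alpha = 2000, 0.05
        r = 1 / alpha
        m_a, m_b = 400.0, 100.0
        a = rng.negative_binomial(r, r / (r + m_a), size=(n_genes, 3))
        b = rng.negative_binomial(r, r / (r + m_b), size=(n_genes, 3))
        design = two_group_design()
        df = pd.DataFrame(np.hstack([a, b]).astype(float),
                          index=[f"g{i}" for i in range(n_genes)],
                          columns=[d.sample_id for d in design])
        disp = estimate_dispersion(df, design)
        res = call_degs(de_test(df, design, ("P1", "P2"), disp))
        assert res["is_deg"].mean() >= 0.90


def brute_force_bh(pvals):
    """Step-up BH from first principles."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


class TestBH:
    def test_step_up_closed_form(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        p = rng.random(100)
        assert bh_adjust(p) == pytest.approx(brute_force_bh(list(p)))

    def test_monotone_in_p(self):
        rng = np.random.default_rng(6)
        p = rng.random(200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(HeteroseqError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.2])


class TestCallDegs:
    @pytest.mark.parametrize(
        "log2fc,fdr,expected",
        [
            (1.0, 0.01, False),  # fold change must strictly exceed 2
            (2.5, 0.049, True),
            (2.5, 0.05, False),  # FDR strictly below 0.05
            (-1.5, 0.001, True),
        ],
    )
    def test_strict_thresholds(self, log2fc, fdr, expected):
        res = pd.DataFrame({"gene_id": ["g"], "log2fc": [log2fc], "pvalue": [fdr], "fdr": [fdr], "is_deg": [False]})
        # feed pvalue=fdr so BH over one gene reproduces the fdr exactly
        out = call_degs(res)
        assert bool(out["is_deg"].iloc[0]) is expected
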