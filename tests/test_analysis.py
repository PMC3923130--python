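"""Tertile bins, stage composition, correlations, TAI/TDI, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from mirevol.analysis import (
    bootstrap_sd,
    breadth_contrast,
    expression_divergence_scatter_stats,
    stage_composition,
    stage_correlation,
    stage_index_profile,
    tai_tdi,
    tertile_bins,
)
from mirevol.expression import ExpressionMatrix, detect_and_breadth, normalize


class TestTertileBins:
    def test_nine_values_split_evenly(self):
        div = pd.Series(np.arange(9) / 10, index=[f"m{i}" for i in range(9)])
        bins, ranges = tertile_bins(div)
        assert [len(b) for b in bins] == [3, 3, 3]
        assert ranges[0][1] <= ranges[1][0] and ranges[1][1] <= ranges[2][0]

    def test_remainder_goes_to_lower_bins(self):
        div = pd.Series(np.arange(10) / 10, index=[f"m{i}" for i in range(10)])
        bins, _ = tertile_bins(div)
        assert [len(b) for b in bins] == [4, 3, 3]

    def test_identical_values_warn_but_split(self):
        div = pd.Series(0.1, index=[f"m{i}" for i in range(6)])
        with pytest.warns(UserWarning):
            bins, _ = tertile_bins(div)
        assert [len(b) for b in bins] == [2, 2, 2]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tertile_bins(pd.Series([0.1, 0.2]))


class TestStageComposition:
    def test_all_expression_in_one_bin(self):
        rpm = pd.DataFrame({"s1": [10.0, 0.0, 0.0]}, index=list("abc"))
        comp = stage_composition(rpm, [["a"], ["b"], ["c"]])
        assert list(comp.loc["s1"]) == [1.0, 0.0, 0.0]

    def test_fractions_sum_to_one(self, default_dataset):
        ds = default_dataset
        div = ds.truth.loc[ds.truth.has_ortholog, "true_hairpin_rate"]
        rpm = normalize(ds.matrix)
        bins, _ = tertile_bins(div)
        comp = stage_composition(rpm, bins)
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_zero_total_stage_flagged_nan(self):
        rpm = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]}, index=list("ab"))
        comp = stage_composition(rpm, [["a"], ["b"]])
        assert comp.loc["s2"].isna().all()


class TestStageCorrelation:
    def _matrix(self, values):
        return ExpressionMatrix(counts=pd.DataFrame(
            {"s1": values}, index=[f"m{i}" for i in range(len(values))]))

    def test_perfectly_antimonotone(self):
        matrix = self._matrix([40.0, 30.0, 20.0, 10.0])
        div = pd.Series([0.1, 0.2, 0.3, 0.4], index=matrix.counts.index)
        rho, p, m = stage_correlation(matrix, div, "s1")
        assert rho == -1.0 and m == 4

    def test_independent_near_zero(self, rng):
        vals = rng.poisson(100, size=500).astype(float) + 1
        matrix = self._matrix(list(vals))
        div = pd.Series(rng.uniform(0, 0.4, 500), index=matrix.counts.index)
        rho, _, _ = stage_correlation(matrix, div, "s1")
        assert abs(rho) < 0.12

    def test_denominator_invariance(self, default_dataset):
        """Spearman per stage is identical under either RPM denominator."""
        ds = default_dataset
        div = ds.truth.loc[ds.truth.has_ortholog, "true_hairpin_rate"]
        for denom in ("mirna_mapped", "genome_mapped"):
            rpm = normalize(ds.matrix, denom)
            rhos = [stage_correlation(ds.matrix, div, s, values=rpm)[0]
                    for s in ds.matrix.stages]
            if denom == "mirna_mapped":
                ref = rhos
        assert np.allclose(ref, rhos)

    def test_zero_variance_rejected(self):
        matrix = self._matrix([5.0, 5.0, 5.0])
        div = pd.Series([0.2, 0.2, 0.2], index=matrix.counts.index)
        with pytest.raises(ValueError):
            stage_correlation(matrix, div, "s1")


class TestBreadthContrast:
    def test_identical_groups_t_zero(self):
        div = pd.Series([0.1, 0.2, 0.3, 0.1, 0.2, 0.3], index=list("abcdef"))
        breadth = pd.Series([11, 11, 11, 5, 5, 5], index=list("abcdef"))
        out = breadth_contrast(div, breadth)
        assert out["t"] == pytest.approx(0.0)

    def test_conserved_broad_negative_rho(self, rng):
        n = 100
        div = pd.Series(rng.uniform(0, 0.4, n), index=[f"m{i}" for i in range(n)])
        breadth = (11 - 20 * div + rng.normal(0, 0.5, n)).round().clip(1, 11)
        out = breadth_contrast(div, pd.Series(breadth, index=div.index))
        assert out["rho"] < 0
        assert out["mean_full_breadth"] < out["mean_partial_breadth"]

    def test_degenerate_zero_variance_flagged(self):
        div = pd.Series([0.1, 0.1, 0.3, 0.3], index=list("abcd"))
        breadth = pd.Series([11, 11, 4, 4], index=list("abcd"))
        out = breadth_contrast(div, breadth)
        assert out["flag"] == "degenerate-zero-variance"
        assert np.isinf(out["t"])

    def test_tiny_group_rejected(self):
        div = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        breadth = pd.Series([11, 11, 11], index=list("abc"))
        with pytest.raises(ValueError):
            breadth_contrast(div, breadth)


class TestScatterStats:
    def test_negative_coupling_recovered(self, default_dataset):
        ds = default_dataset
        div = ds.truth.loc[ds.truth.has_ortholog, "true_hairpin_rate"]
        rpm = normalize(ds.matrix)
        r_sum, p_sum = expression_divergence_scatter_stats(rpm, div, "sum")
        r_max, _ = expression_divergence_scatter_stats(rpm, div, "max")
        assert r_sum < 0 and p_sum < 1e-3
        assert np.sign(r_sum) == np.sign(r_max)

    def test_constant_divergence_rejected(self):
        rpm = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=list("abc"))
        div = pd.Series(0.2, index=list("abc"))
        with pytest.raises(ValueError):
            expression_divergence_scatter_stats(rpm, div)


class TestTaiTdi:
    def test_constant_weights_give_constant(self, rng):
        e = pd.Series(rng.uniform(1, 1000, 50), index=[f"m{i}" for i in range(50)])
        ages = pd.Series(4.0, index=e.index)
        assert tai_tdi(e, ages) == pytest.approx(4.0)

    def test_weighted_mean_example(self):
        e = pd.Series({"x": 100.0, "y": 300.0})
        ages = pd.Series({"x": 2.0, "y": 6.0})
        assert tai_tdi(e, ages) == pytest.approx(5.0)

    def test_scale_invariance(self, rng):
        e = pd.Series(rng.uniform(1, 1000, 30))
        w = pd.Series(rng.uniform(1, 7, 30))
        assert tai_tdi(e, w) == pytest.approx(tai_tdi(e * 17.3, w))

    def test_bounded_by_weight_range(self, rng):
        e = pd.Series(rng.uniform(0, 100, 40))
        w = pd.Series(rng.integers(1, 8, 40).astype(float))
        val = tai_tdi(e, w)
        assert w.min() <= val <= w.max()

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tai_tdi(pd.Series({"x": 0.0}), pd.Series({"x": 3.0}))


class TestBootstrap:
    def test_equal_weights_sd_zero(self, rng):
        e = pd.Series(rng.uniform(1, 100, 25))
        w = pd.Series(3.0, index=e.index)
        assert bootstrap_sd(e, w, n_boot=1000, seed=0) == 0.0

    def test_stable_under_more_replicates(self, rng):
        e = pd.Series(rng.uniform(1, 100, 60))
        w = pd.Series(rng.integers(1, 8, 60).astype(float), index=e.index)
        sd1 = bootstrap_sd(e, w, n_boot=1000, seed=1)
        sd2 = bootstrap_sd(e, w, n_boot=2000, seed=1)
        assert sd1 == pytest.approx(sd2, rel=0.15)

    def test_sd_decreases_with_more_mirnas(self, rng):
        big_e = pd.Series(rng.uniform(1, 100, 400))
        big_w = pd.Series(rng.uniform(1, 7, 400), index=big_e.index)
        small_e = big_e.iloc[:25]
        small_w = big_w.iloc[:25]
        assert (bootstrap_sd(big_e, big_w, 1000, 2)
                < bootstrap_sd(small_e, small_w, 1000, 2))


def test_stage_index_profile_shape(default_dataset):
    ds = default_dataset
    div = ds.truth.loc[ds.truth.has_ortholog, "true_hairpin_rate"]
    ages = ds.truth.loc[ds.truth.has_ortholog, "age_rank"].astype(float)
    prof = stage_index_profile(ds.matrix, ages, div, n_boot=100, seed=0)
    t = prof.table
    assert list(t.index) == list(ds.matrix.stages)
    assert ((t.tai >= 1) & (t.tai <= 7)).all()
    assert (t.tdi >= 0).all()
    assert ((t.rho >= -1) & (t.rho <= 1)).all()
    assert (t[["tai_sd", "tdi_sd"]] >= 0).all().all()
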