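import numpy as np
import pandas as pd
import pytest

import gdnaclean as gd
from gdnaclean.correction import (
    CorrectionError,
    GCCorrector,
    IRPercentCorrector,
    gc_bin_index,
)


class TestGlobalFpb:
    def test_median_over_nonzero_regions(self):
        counts = pd.Series([1, 0, 4], index=["r1", "r2", "r3"])
        lengths = pd.Series([100.0, 200, 400], index=counts.index)
        assert gd.estimate_global_fpb(counts, lengths) == pytest.approx(0.01)

    def test_constant_coverage(self):
        counts = pd.Series([10, 20, 40], index=["r1", "r2", "r3"])
        lengths = pd.Series([100.0, 200, 400], index=counts.index)
        assert gd.estimate_global_fpb(counts, lengths) == pytest.approx(0.1)

    def test_all_zero_counts_error_says_correction_unnecessary(self):
        counts = pd.Series([0, 0], index=["r1", "r2"])
        lengths = pd.Series([100.0, 100.0], index=counts.index)
        with pytest.raises(CorrectionError, match="unnecessary"):
            gd.estimate_global_fpb(counts, lengths)


class TestGlobalCorrection:
    def test_subtraction_arithmetic(self):
        counts = pd.DataFrame({"s": [50]}, index=["g"])
        out = gd.global_correction(counts, pd.Series({"s": 0.01}), lengths=pd.Series({"g": 1000.0}))
        assert out.matrix.loc["g", "s"] == 40

    def test_clamped_at_zero(self):
        counts = pd.DataFrame({"s": [5]}, index=["g"])
        out = gd.global_correction(counts, pd.Series({"s": 0.01}), lengths=pd.Series({"g": 1000.0}))
        assert out.matrix.loc["g", "s"] == 0

    def test_zero_fpb_is_identity(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (20, 3)), columns=list("abc"))
        lengths = pd.Series(rng.integers(500, 5000, 20).astype(float))
        out = gd.global_correction(counts, pd.Series(0.0, index=list("abc")), lengths=lengths)
        assert (out.matrix.values == counts.values).all()

    def test_missing_length_lists_genes(self):
        counts = pd.DataFrame({"s": [5, 5]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 100.0})
        with pytest.raises(CorrectionError, match="g2"):
            gd.global_correction(counts, pd.Series({"s": 0.01}), lengths=lengths)


class TestGcBinning:
    def test_bin_edges(self):
        assert gc_bin_index([0.42])[0] == 8
        assert gc_bin_index([1.0])[0] == 19  # last bin closed
        assert gc_bin_index([0.0])[0] == 0
        assert gc_bin_index([np.nan])[0] == -1


class TestGcModel:
    def _regions(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        gc = np.linspace(0.05, 0.95, n)
        lengths = pd.Series(1000.0, index=[f"r{i}" for i in range(n)])
        return gc, lengths

    def test_flat_coverage_reduces_to_global(self):
        gc, lengths = self._regions()
        counts = pd.Series(8, index=lengths.index)  # FPB = 0.008 everywhere
        est = gd.fit_gc_model(counts, lengths, pd.Series(gc, index=lengths.index))
        assert est == pytest.approx(np.full(20, 0.008), rel=1e-6)

    def test_linear_truth_gives_monotone_bins(self):
        gc, lengths = self._regions()
        fpb = 0.002 + 0.02 * gc
        counts = pd.Series(np.rint(fpb * 1000).astype(int), index=lengths.index)
        est = gd.fit_gc_model(counts, lengths, pd.Series(gc, index=lengths.index))
        assert (np.diff(est) >= -1e-9).all()
        assert est[-1] > est[0]

    def test_too_few_regions_falls_back_to_global_with_warning(self):
        lengths = pd.Series(1000.0, index=[f"r{i}" for i in range(10)])
        counts = pd.Series(5, index=lengths.index)
        gc = pd.Series(np.linspace(0.3, 0.7, 10), index=lengths.index)
        with pytest.warns(UserWarning, match="falling back"):
            est = gd.fit_gc_model(counts, lengths, gc)
        assert est == pytest.approx(np.full(20, 0.005))


class TestGcCorrection:
    def test_flat_bins_reduce_exactly_to_global(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 200, (30, 4)), columns=list("abcd"))
        lengths = pd.Series(rng.integers(300, 4000, 30).astype(float))
        gene_gc = pd.Series(rng.uniform(0, 1, 30))
        fpb = pd.Series([0.01, 0.02, 0.0, 0.005], index=list("abcd"))
        flat = pd.DataFrame(
            np.repeat(fpb.values[None, :], 20, axis=0), columns=list("abcd")
        )
        out_gc = gd.gc_correction(counts, flat, gene_gc, lengths=lengths)
        out_gl = gd.global_correction(counts, fpb, lengths=lengths)
        assert (out_gc.matrix.values == out_gl.matrix.values).all()

    def test_undefined_gene_gc_falls_back_to_global(self):
        counts = pd.DataFrame({"s": [100]}, index=["g"])
        bins = pd.DataFrame({"s": np.linspace(0, 0.019, 20)})
        out = gd.gc_correction(
            counts, bins, pd.Series({"g": np.nan}), lengths=pd.Series({"g": 1000.0}),
            global_fpb=pd.Series({"s": 0.01}),
        )
        assert out.matrix.loc["g", "s"] == 90

    def test_corrected_counts_are_nonnegative_integers(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 50, (40, 3)), columns=list("abc"))
        lengths = pd.Series(rng.integers(200, 9000, 40).astype(float))
        gene_gc = pd.Series(rng.uniform(0, 1, 40))
        bins = pd.DataFrame(rng.uniform(0, 0.01, (20, 3)), columns=list("abc"))
        out = gd.gc_correction(counts, bins, gene_gc, lengths=lengths)
        assert (out.matrix.values >= 0).all()
        assert np.issubdtype(out.matrix.values.dtype, np.integer)


class TestIRPercentCorrection:
    def test_log2cpm_closed_form_for_zero_count(self):
        counts = pd.DataFrame(
            {"a": [0, 1_000_000], "b": [100, 999_900], "c": [50, 999_950]},
            index=["g0", "g1"],
        )
        ir = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        est = IRPercentCorrector()
        est.fit_transform(counts, ir)
        # y = log2(0.5 / (1e6 + 1) * 1e6)
        assert est.log2cpm_.loc["g0", "a"] == pytest.approx(
            np.log2(0.5 / 1_000_001 * 1e6)
        )

    def test_null_case_leaves_matrix_unchanged(self):
        # identical columns within each group: the group fit is exact, the
        # IR% coefficient is identically zero, adjustment is a no-op
        col1 = [10, 200, 3000, 40]
        col2 = [20, 100, 2500, 80]
        counts = pd.DataFrame(
            {"a1": col1, "a2": col1, "a3": col1, "b1": col2, "b2": col2, "b3": col2}
        )
        groups = pd.Series(
            ["A", "A", "A", "B", "B", "B"], index=counts.columns
        )
        ir = pd.Series([1.0, 1.1, 0.9, 5.0, 5.2, 4.8], index=counts.columns)
        est = IRPercentCorrector()
        adjusted = est.fit_transform(counts, ir, groups=groups)
        assert np.abs(adjusted.values - est.log2cpm_.values).max() < 1e-9
        assert np.abs(est.beta_ir_.values).max() < 1e-9

    def test_constant_ir_is_an_error(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(CorrectionError, match="uninformative"):
            IRPercentCorrector().fit_transform(counts, pd.Series({"a": 5.0, "b": 5.0}))

    def test_collinear_design_names_the_columns(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [3, 4], "c": [5, 6], "d": [7, 8]})
        groups = pd.Series(["x", "x", "y", "y"], index=counts.columns)
        ir = pd.Series([1.0, 1.0, 4.0, 4.0], index=counts.columns)  # in span of groups
        with pytest.raises(CorrectionError, match="ir_centered"):
            IRPercentCorrector().fit_transform(counts, ir, groups=groups)

    def test_removes_contamination_driven_correlation(self, analog_bundle):
        b = analog_bundle
        est = IRPercentCorrector()
        adjusted = est.fit_transform(b.expression.counts, b.ir_percent)
        y = est.log2cpm_
        irc = (b.ir_percent - b.ir_percent.mean()).values

        def corrs(M):
            X = M.values - M.values.mean(axis=1, keepdims=True)
            den = np.sqrt((X**2).sum(axis=1) * (irc**2).sum())
            return np.where(den > 0, X @ irc / den, 0.0)

        before = corrs(y)
        hot = np.abs(before) > 0.5
        assert hot.sum() > 10  # contamination leaves a visible footprint
        assert np.abs(corrs(adjusted)[hot]).mean() < 0.1


class TestStranded:
    def test_subtraction(self):
        s = pd.DataFrame({"x": [100, 5, 7]})
        a = pd.DataFrame({"x": [40, 10, 0]})
        out = gd.stranded_correction(s, a)
        assert out.matrix["x"].tolist() == [60, 0, 7]

    def test_mismatched_ids_error(self):
        s = pd.DataFrame({"x": [1]}, index=["g1"])
        a = pd.DataFrame({"x": [1]}, index=["g2"])
        with pytest.raises(CorrectionError):
            gd.stranded_correction(s, a)


class TestFilters:
    def test_multiexonic_without_junctions_dropped_monoexonic_kept(self):
        m = pd.DataFrame({"s1": [5, 5, 5], "s2": [5, 5, 5]}, index=["multi0", "mono0", "multi3"])
        n_exons = pd.Series({"multi0": 2, "mono0": 1, "multi3": 3})
        support = pd.DataFrame(
            {"s1": [0, 0, 3], "s2": [0, 0, 0]}, index=m.index
        )
        out = gd.filter_unsupported_multiexonic(m, n_exons, support, min_junction_fragments=1)
        assert list(out.index) == ["mono0", "multi3"]

    def test_low_in_clean_hand_evaluated(self):
        # 5 genes x 4 samples; conditions X (a1 clean, a2 contaminated),
        # Y (b1 clean, b2 contaminated); library sizes equal so CPM ~ counts
        m = pd.DataFrame(
            {
                "a1": [0, 50, 0, 0, 9950],
                "a2": [50, 0, 50, 0, 9900],
                "b1": [0, 0, 60, 0, 9940],
                "b2": [0, 0, 0, 50, 9950],
            },
            index=[f"g{i}" for i in range(5)],
        )
        cond = pd.Series({"a1": "X", "a2": "X", "b1": "Y", "b2": "Y"})
        flags = pd.Series({"a1": False, "a2": True, "b1": False, "b2": True})
        out = gd.filter_low_in_clean(m, cond, flags, cpm_cutoff=1.0)
        # g0 expressed only in contaminated samples -> dropped; g1 passes via a1,
        # g2 via b1, g3 nowhere clean -> dropped, g4 everywhere
        assert list(out.index) == ["g1", "g2", "g4"]

    def test_condition_without_clean_sample_is_an_error(self):
        m = pd.DataFrame({"a": [1], "b": [1]})
        cond = pd.Series({"a": "X", "b": "Y"})
        flags = pd.Series({"a": False, "b": True})
        with pytest.raises(CorrectionError, match="Y"):
            gd.filter_low_in_clean(m, cond, flags)
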