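import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from threebias import (
    GeneAnnotation,
    MethodResult,
    SimConfig,
    consensus,
    length_logfc_diagnostic,
    method1_threeprime,
    method2_binned_tmm,
    method3_slope_align,
    run_consensus_pipeline,
    run_de,
    simulate_counts,
)
from threebias.bias import _length_bins
from conftest import TWO_GROUP_DESIGN


def make_methods(lfc_triples, pvals=None):
    """MethodResult trio from per-gene (m1, m2, m3) log fold changes."""
    genes = [f"g{i}" for i in range(len(lfc_triples))]
    arr = np.asarray(lfc_triples, dtype=float)
    if pvals is None:
        pvals = np.full(arr.shape, 0.01)
    out = []
    for k, mid in enumerate(("threeprime", "binned_tmm", "slope_only")):
        out.append(
            MethodResult(
                mid,
                pd.DataFrame(
                    {"log_fc": arr[:, k], "p_value": np.asarray(pvals)[:, k]},
                    index=genes,
                ),
            )
        )
    return out


class TestSlopeAlign:
    def test_closed_form_ols(self):
        lengths = pd.Series([10.0, 100.0, 1000.0], index=["a", "b", "c"])
        lfc = pd.Series([2.0, 4.0, 6.0], index=["a", "b", "c"])
        adjusted = method3_slope_align(lfc, lengths)
        assert np.allclose(adjusted, [4.0, 4.0, 4.0])

    def test_uncorrelated_input_unchanged(self):
        lengths = pd.Series([10.0, 100.0, 1000.0], index=list("abc"))
        lfc = pd.Series([1.0, 3.0, 1.0], index=list("abc"))
        adjusted = method3_slope_align(lfc, lengths)
        # slope is exactly 0 for this symmetric configuration
        assert np.allclose(adjusted, lfc)

    def test_mean_preserved_and_residual_slope_zero(self):
        rng = np.random.default_rng(0)
        lengths = pd.Series(10 ** rng.uniform(2, 5, 200))
        lfc = pd.Series(0.8 * np.log10(lengths.to_numpy()) + rng.normal(0, 0.3, 200))
        adjusted = method3_slope_align(lfc, lengths)
        assert adjusted.mean() == pytest.approx(lfc.mean(), abs=1e-9)
        diag = length_logfc_diagnostic(adjusted, lengths)
        assert abs(diag["slope"]) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        lengths = pd.Series(10 ** rng.uniform(2, 5, 100))
        lfc = pd.Series(rng.normal(0, 1, 100) - np.log10(lengths.to_numpy()))
        once = method3_slope_align(lfc, lengths)
        twice = method3_slope_align(once, lengths)
        assert np.allclose(once, twice, atol=1e-12)

    def test_equal_lengths_warns_and_returns_input(self):
        lengths = pd.Series([500.0] * 5)
        lfc = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning, match="slope undefined"):
            adjusted = method3_slope_align(lfc, lengths)
        assert np.allclose(adjusted, lfc)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="3 genes"):
            method3_slope_align(pd.Series([1.0, 2.0]), pd.Series([10.0, 20.0]))


class TestConsensus:
    def test_sign_conflict_is_zeroed(self):
        cons = consensus(*make_methods([(0.5, 0.8, -0.2)]))
        row = cons.table.iloc[0]
        assert row.consensus_log_fc == 0.0
        assert row.chosen_method == "zeroed"
        assert row.consensus_p == 1.0

    def test_minimum_absolute_value_wins(self):
        cons = consensus(*make_methods([(1.2, 0.7, 0.9)]))
        row = cons.table.iloc[0]
        assert row.consensus_log_fc == pytest.approx(0.7)
        assert row.chosen_method == "binned_tmm"

    def test_all_zero_is_agreement_not_conflict(self):
        cons = consensus(*make_methods([(0.0, 0.0, 0.0)]))
        row = cons.table.iloc[0]
        assert row.consensus_log_fc == 0.0
        assert row.chosen_method != "zeroed"

    def test_chosen_method_p_is_carried(self):
        pvals = [[0.5, 0.001, 0.9]]
        cons = consensus(*make_methods([(1.2, 0.7, 0.9)], pvals))
        assert cons.table.iloc[0].consensus_p == pytest.approx(0.001)

    def test_gene_set_mismatch_rejected(self):
        m1, m2, m3 = make_methods([(1.0, 1.0, 1.0), (2.0, 2.0, 2.0)])
        m3 = MethodResult("slope_only", m3.table.iloc[:1])
        with pytest.raises(ValueError, match="gene set"):
            consensus(m1, m2, m3)

    @given(
        st.lists(
            st.tuples(*[st.floats(-3, 3, allow_nan=False)] * 3),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_conservativeness_and_sign_safety(self, triples):
        cons = consensus(*make_methods(triples))
        arr = np.asarray(triples)
        out = cons.table.consensus_log_fc.to_numpy()
        # conservativeness: never larger in magnitude than any method
        assert (np.abs(out) <= np.abs(arr).min(axis=1) + 1e-12).all()
        # sign safety: never opposite in sign to a contributing method
        assert (out[:, None] * arr >= -1e-12).all()
        # zeroed genes carry p = 1
        zeroed = cons.table.chosen_method == "zeroed"
        assert (cons.table.consensus_p[zeroed] == 1.0).all()


class TestLengthBins:
    def test_equal_count_deciles(self):
        lengths = pd.Series(
            10 ** np.linspace(2, 5, 2000), index=[f"g{i}" for i in range(2000)]
        )
        bins = _length_bins(lengths, 10)
        assert (bins.value_counts() == 200).all()

    def test_small_bins_merged_with_warning(self):
        lengths = pd.Series(
            10 ** np.linspace(2, 4, 12), index=[f"g{i}" for i in range(12)]
        )
        with pytest.warns(UserWarning, match="merging"):
            bins = _length_bins(lengths, 3)
        assert (bins.value_counts() >= 5).all()


class TestMethod1:
    def test_window_covering_all_transcripts_matches_uncorrected(
        self, null_experiment
    ):
        exp = null_experiment
        # windowed counts generated with W > max length equal the full counts
        big_window = float(exp.annotation.lengths.max() + 1)
        res = method1_threeprime(
            exp.counts, exp.annotation, window=big_window
        )
        plain = run_de(exp.counts)
        assert np.allclose(res.log_fc, plain.log_fc)
        assert np.allclose(res.p_value, plain.p_value)

    def test_all_zero_windowed_counts_warn_empty(self, null_experiment):
        exp = null_experiment
        zero = exp.counts
        zero = type(zero)(zero.counts * 0, zero.sample_meta)
        with pytest.warns(UserWarning, match="all zero"):
            res = method1_threeprime(zero, exp.annotation)
        assert len(res.table) == 0


class TestMethod2:
    def test_single_bin_equal_lengths_matches_global_pipeline(self):
        cfg = SimConfig(
            n_genes=300, design=TWO_GROUP_DESIGN, dispersion=0.1,
            length_log10_range=(3.0, 3.0), lib_size=3e5, seed=23,
        )
        exp = simulate_counts(cfg)
        with pytest.warns(UserWarning, match="slope undefined"):
            res = method2_binned_tmm(
                exp.counts, exp.annotation, n_bins=1
            )
        plain = run_de(exp.counts)
        assert np.allclose(res.log_fc, plain.log_fc)
        assert np.allclose(res.p_value, plain.p_value)

    def test_post_alignment_slope_is_zero(self, biased_null_experiment):
        exp = biased_null_experiment
        res = method2_binned_tmm(exp.counts, exp.annotation, n_bins=10)
        diag = length_logfc_diagnostic(
            res.log_fc, exp.annotation.for_genes(res.gene_ids)
        )
        assert abs(diag["slope"]) < 1e-9

    def test_too_few_genes_rejected(self, simple_annotation):
        cfg = SimConfig(n_genes=20, design=TWO_GROUP_DESIGN, seed=1)
        exp = simulate_counts(cfg)
        with pytest.raises(ValueError, match="bins"):
            method2_binned_tmm(exp.counts, exp.annotation, n_bins=10)


class TestDiagnostics:
    def test_perfect_linear_relation(self):
        lengths = pd.Series(10 ** np.linspace(2, 4, 50))
        lfc = pd.Series(2 * np.log10(lengths.to_numpy()))
        diag = length_logfc_diagnostic(lfc, lengths)
        assert diag["r"] == pytest.approx(1.0)
        assert diag["slope"] == pytest.approx(2.0)

    def test_constant_logfc_gives_zero_slope(self):
        lengths = pd.Series(10 ** np.linspace(2, 4, 50))
        diag = length_logfc_diagnostic(pd.Series(np.ones(50)), lengths)
        assert diag["slope"] == 0.0
        assert diag["degenerate"]

    def test_differential_bias_direction(self, biased_null_experiment):
        # treated (torin) has stronger decay (tau 1000 < 4000): long
        # transcripts lose relatively more reads, so LogFC trends negative
        exp = biased_null_experiment
        res = run_de(exp.counts)
        diag = length_logfc_diagnostic(
            res.log_fc, exp.annotation.for_genes(res.gene_ids)
        )
        assert diag["r"] < -0.2
        assert diag["slope"] < 0


class TestPipeline:
    def test_bias_correction_shrinks_length_correlation(self, biased_null_experiment):
        exp = biased_null_experiment
        res = run_consensus_pipeline(exp.counts, exp.windowed_counts, exp.annotation)
        d = res["diagnostics"]
        assert abs(d["uncorrected"]["r"]) > 0.2
        for mid in ("threeprime", "binned_tmm", "slope_only", "consensus"):
            assert abs(d[mid]["r"]) < abs(d["uncorrected"]["r"])

    def test_consensus_table_well_formed(self, biased_null_experiment):
        exp = biased_null_experiment
        res = run_consensus_pipeline(exp.counts, exp.windowed_counts, exp.annotation)
        cons = res["consensus"]
        methods = res["methods"]
        stack = np.column_stack(
            [methods[m].log_fc.to_numpy() for m in methods]
        )
        assert (np.abs(cons.log_fc.to_numpy()) <= np.abs(stack).min(axis=1) + 1e-12).all()
        assert ((cons.fdr >= 0) & (cons.fdr <= 1)).all()
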