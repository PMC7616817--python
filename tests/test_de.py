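"""Normalization, dispersion, Wald testing, BH and midparent values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from polyshock import de, simulate


def _sheet(samples, strain="x"):
    return pd.DataFrame(
        {
            "strain": strain,
            "generation": "NA",
            "line": "NA",
            "replicate": range(1, len(samples) + 1),
        },
        index=pd.Index(samples, name="sample"),
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 101)
        counts = pd.DataFrame({"a": col, "b": col})
        f = de.size_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_doubled_column_splits_symmetrically(self):
        col = np.arange(1, 101)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        f = de.size_factors(counts)
        np.testing.assert_allclose(
            f.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.05, size=(300, 6)),
            columns=[f"s{j}" for j in range(6)],
        )
        f = de.size_factors(counts)
        # independent reference: explicit loop over all-positive genes
        mat = counts.to_numpy(dtype=float)
        keep = [i for i in range(len(mat)) if all(mat[i] > 0)]
        ref = []
        for j in range(mat.shape[1]):
            ratios = []
            for i in keep:
                geo = np.exp(np.mean([np.log(v) for v in mat[i]]))
                ratios.append(mat[i, j] / geo)
            ref.append(np.median(ratios))
        ref = np.array(ref)
        ref = ref / np.exp(np.mean(np.log(ref)))
        np.testing.assert_allclose(f.to_numpy(), ref, rtol=1e-12)

    def test_geometric_mean_one_invariant(self, small_counts):
        f = de.size_factors(small_counts)
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-12

    def test_all_zero_matrix_rejected(self):
        counts = pd.DataFrame(np.zeros((5, 3), dtype=int))
        with pytest.raises(ValueError):
            de.size_factors(counts)


class TestNormalize:
    def test_identity_factors_leave_matrix_unchanged(self, small_counts):
        f = pd.Series(1.0, index=small_counts.columns)
        pd.testing.assert_frame_equal(
            de.normalize(small_counts, f), small_counts.astype(float)
        )

    def test_factor_two_halves_a_column(self, small_counts):
        f = pd.Series(1.0, index=small_counts.columns)
        f.iloc[0] = 2.0
        norm = de.normalize(small_counts, f)
        np.testing.assert_allclose(
            norm.iloc[:, 0], small_counts.iloc[:, 0] / 2.0
        )

    def test_nonpositive_factor_rejected(self, small_counts):
        f = pd.Series(1.0, index=small_counts.columns)
        f.iloc[1] = 0.0
        with pytest.raises(ValueError):
            de.normalize(small_counts, f)


class TestDispersion:
    def test_poisson_data_yields_near_zero_dispersion(self):
        design = simulate.SimDesign(
            n_genes=2000,
            groups=[("1N_parent", "NA", "NA", 6), ("2N_parent", "NA", "NA", 6)],
            dispersion=0.0,
            lib_size_cv=0.0,
            seed=2,
        )
        counts, sheet, _ = simulate.simulate_counts(design, {})
        groups = [list(sheet.index[:6]), list(sheet.index[6:])]
        disp = de.estimate_dispersion(counts, groups)
        assert disp["phi"].median() <= 0.01

    def test_nb_dispersion_recovered(self):
        design = simulate.SimDesign(
            n_genes=2000,
            groups=[("1N_parent", "NA", "NA", 6), ("2N_parent", "NA", "NA", 6)],
            dispersion=0.5,
            lib_size_cv=0.0,
            seed=3,
        )
        counts, sheet, _ = simulate.simulate_counts(design, {})
        groups = [list(sheet.index[:6]), list(sheet.index[6:])]
        disp = de.estimate_dispersion(counts, groups)
        assert 0.4 <= disp["phi"].median() <= 0.6

    def test_constant_gene_has_zero_raw_dispersion(self):
        counts = pd.DataFrame(
            {"a": [10, 100], "b": [10, 80], "c": [10, 120], "d": [10, 90]}
        )
        disp = de.estimate_dispersion(
            counts, [["a", "b"], ["c", "d"]],
            factors=pd.Series(1.0, index=counts.columns),
        )
        assert disp.loc[0, "phi_raw"] == 0.0

    def test_single_replicate_rejected(self, small_counts):
        with pytest.raises(ValueError):
            de.estimate_dispersion(small_counts, [["s1"], ["s2", "s3"]])


class TestBH:
    def test_closed_form_triple(self):
        np.testing.assert_allclose(
            de.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], rtol=1e-15
        )

    def test_single_p_unchanged(self):
        assert de.adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=500)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(de.adjust_bh(p), ref, atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.adjust_bh([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=40)
    )
    def test_preserves_p_value_ordering(self, pvals):
        p = np.array(pvals)
        adj = de.adjust_bh(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)


class TestWald:
    def test_same_group_vs_itself_is_null(self, small_counts):
        sheet = _sheet(small_counts.columns)
        tab = de.wald_test(
            small_counts, sheet, ["s1", "s2"], ["s1", "s2"], alpha=0.01
        )
        assert (tab["log2fc"] == 0).all()
        assert (tab["pvalue"] == 1.0).all()

    def test_group_swap_negates_logfc_and_keeps_p(self, small_counts):
        sheet = _sheet(small_counts.columns)
        a, b = ["s1", "s2"], ["s3", "s4"]
        t1 = de.wald_test(small_counts, sheet, a, b, alpha=0.01)
        t2 = de.wald_test(small_counts, sheet, b, a, alpha=0.01)
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"], atol=1e-12)
        np.testing.assert_allclose(t1["pvalue"], t2["pvalue"], atol=1e-12)

    def test_unknown_group_label_rejected(self, small_counts):
        sheet = _sheet(small_counts.columns)
        with pytest.raises(KeyError):
            de.wald_test(small_counts, sheet, "nope", ["s1", "s2"])

    def test_all_zero_gene_reported_with_p_one(self, small_counts):
        counts = small_counts.copy()
        counts.iloc[0] = 0
        sheet = _sheet(counts.columns)
        tab = de.wald_test(counts, sheet, ["s1", "s2"], ["s3", "s4"])
        assert tab["pvalue"].iloc[0] == 1.0
        assert tab["log2fc"].iloc[0] == 0.0


class TestMidparent:
    def test_arithmetic_mean_of_parents(self):
        counts = pd.DataFrame(
            {"p1a": [10, 10], "p1b": [10, 10], "p2a": [30, 30], "p2b": [30, 30]}
        )
        sheet = _sheet(counts.columns)
        f = pd.Series(1.0, index=counts.columns)
        mpv = de.midparent(
            counts, sheet, ["p1a", "p1b"], ["p2a", "p2b"], factors=f
        )
        np.testing.assert_allclose(mpv.to_numpy(), 20.0)
        assert mpv.shape[1] == 2

    def test_identical_parents_idempotent(self, small_counts):
        sheet = _sheet(small_counts.columns)
        f = pd.Series(1.0, index=small_counts.columns)
        mpv = de.midparent(
            small_counts, sheet, ["s1", "s2"], ["s1", "s2"], seed=5, factors=f
        )
        # every pseudo-replicate is a convex combination of identical tables
        for col in mpv.columns:
            assert (mpv[col] >= small_counts[["s1", "s2"]].min(axis=1) - 1e-9).all()
            assert (mpv[col] <= small_counts[["s1", "s2"]].max(axis=1) + 1e-9).all()

    def test_unequal_weights_on_equal_parents(self):
        counts = pd.DataFrame({"p1": [30], "q1": [30], "p2": [30], "q2": [30]})
        sheet = _sheet(counts.columns)
        f = pd.Series(1.0, index=counts.columns)
        mpv = de.midparent(
            counts, sheet, ["p1", "q1"], ["p2", "q2"], weights=(1 / 3, 2 / 3),
            factors=f,
        )
        np.testing.assert_allclose(mpv.to_numpy(), 30.0)

    def test_weights_must_sum_to_one(self, small_counts):
        sheet = _sheet(small_counts.columns)
        with pytest.raises(ValueError):
            de.midparent(
                small_counts, sheet, ["s1"], ["s2"], weights=(0.5, 0.6)
            )
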