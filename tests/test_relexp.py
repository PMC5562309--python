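"""Percent-of-pool normalization, profiles, reference, deviation maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import ribodereg as rd


def matrix_from(values, genes=None, groups=None):
    values = np.asarray(values, dtype=float)
    gene_set = genes or rd.GeneSet("g", tuple(f"G{i}" for i in range(values.shape[0])))
    samples = [f"S{j}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, index=gene_set.index(), columns=samples)
    return rd.ExpressionMatrix(gene_set, data, groups or {s: "all" for s in samples})


class TestRelativePercent:
    def test_equal_counts_give_equal_shares(self):
        rel = rd.relative_percent(matrix_from(np.full((4, 2), 7.0)))
        assert np.allclose(rel.values, 25.0)

    def test_forced_arithmetic(self):
        rel = rd.relative_percent(matrix_from([[10], [30], [60]]))
        assert rel.values[:, 0].tolist() == [10.0, 30.0, 60.0]

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="S1"):
            rd.relative_percent(matrix_from([[1, 0], [2, 0]]))

    @given(
        values=arrays(
            float, (5, 3), elements=st.floats(0.01, 1e6, allow_nan=False, allow_infinity=False)
        ),
        scales=arrays(float, (3,), elements=st.floats(0.001, 1000)),
    )
    def test_scale_invariance_per_sample(self, values, scales):
        base = rd.relative_percent(matrix_from(values))
        scaled = rd.relative_percent(matrix_from(values * scales[None, :]))
        assert np.allclose(base.values, scaled.values, rtol=1e-9)

    @given(
        values=arrays(
            float, (6, 4), elements=st.floats(0.01, 1e6, allow_nan=False, allow_infinity=False)
        )
    )
    def test_columns_sum_to_100(self, values):
        rel = rd.relative_percent(matrix_from(values))
        assert np.allclose(rel.values.sum(axis=0), 100.0, rtol=1e-9)


class TestGroupProfiles:
    def test_single_sample_group_is_identity(self, rel_small):
        tumor_only = rel_small.subset_samples(["T1"])
        (profile,) = rd.group_profiles(tumor_only)
        assert np.allclose(profile.mean_rel, rel_small.rel["T1"])

    def test_two_sample_mean(self):
        m = matrix_from([[20, 40], [80, 60]], groups={"S0": "g", "S1": "g"})
        (profile,) = rd.group_profiles(rd.relative_percent(m))
        assert profile.mean_rel.tolist() == [30.0, 70.0]
        assert profile.n_samples == 2

    def test_profiles_sum_to_100(self, rel_small):
        for profile in rd.group_profiles(rel_small):
            assert np.isclose(profile.mean_rel.sum(), 100.0, rtol=1e-9)


class TestNormalReference:
    def test_identical_columns_give_zero_sigma(self):
        m = matrix_from([[10, 10], [90, 90]], groups={"S0": "n", "S1": "n"})
        ref = rd.normal_reference(rd.relative_percent(m))
        assert np.allclose(ref.sigma, 0.0)

    def test_hand_computed_mu_sigma(self):
        # gene shares 40/60 across two normals: mu 50, sigma sqrt(200)
        m = matrix_from([[40, 60], [60, 40]], groups={"S0": "n", "S1": "n"})
        ref = rd.normal_reference(rd.relative_percent(m))
        assert np.allclose(ref.mu, [50.0, 50.0])
        assert np.allclose(ref.sigma, 14.142135623730951)

    def test_permutation_invariance(self, rel_small):
        normals = rel_small.subset_samples(["N1", "N2"])
        flipped = rel_small.subset_samples(["N2", "N1"])
        r1, r2 = rd.normal_reference(normals), rd.normal_reference(flipped)
        pd.testing.assert_series_equal(r1.mu, r2.mu)
        pd.testing.assert_series_equal(r1.sigma, r2.sigma)

    def test_single_sample_rejected(self, rel_small):
        with pytest.raises(ValueError, match=">= 2"):
            rd.normal_reference(rel_small.subset_samples(["N1"]))


class TestDeviationMap:
    def test_tumor_equal_to_mu_gives_zero(self, rel_small, reference_small):
        mu_as_matrix = rd.RelativeExpressionMatrix(
            rel_small.gene_set,
            pd.DataFrame({"T": reference_small.mu}),
            {"T": "tumor"},
        )
        dev = rd.percent_deviation_map(mu_as_matrix, reference_small)
        assert np.allclose(dev.to_numpy(), 0.0)

    def test_double_mu_is_plus_100_percent(self, abc_genes):
        ref = rd.NormalReference(
            abc_genes,
            pd.Series([20.0, 30.0, 50.0], index=abc_genes.index()),
            pd.Series([1.0, 1.0, 1.0], index=abc_genes.index()),
            5,
        )
        rel = rd.RelativeExpressionMatrix(
            abc_genes,
            pd.DataFrame({"T": [40.0, 25.0, 35.0]}, index=abc_genes.index()),
            {"T": "t"},
        )
        dev = rd.percent_deviation_map(rel, ref)
        assert np.isclose(dev.at["A", "T"], 100.0)

    def test_exclude_removes_exactly_those_rows(self):
        genes = rd.GeneSet("rp", ("Rps26", "Rpl9", "Rps27", "Rps28", "Rpl21", "Rpl5", "Rpl11"))
        rng = np.random.default_rng(0)
        raw = matrix_from(rng.uniform(1, 100, (7, 3)), genes=genes,
                          groups={f"S{j}": "n" for j in range(3)})
        rel = rd.relative_percent(raw)
        ref = rd.normal_reference(rel)
        exclude = ("Rps26", "Rpl9", "Rps27", "Rps28", "Rpl21")
        dev = rd.percent_deviation_map(rel, ref, exclude=exclude)
        assert list(dev.index) == ["Rpl5", "Rpl11"]

    def test_zero_mu_row_is_nan_with_warning(self, abc_genes):
        ref = rd.NormalReference(
            abc_genes,
            pd.Series([0.0, 40.0, 60.0], index=abc_genes.index()),
            pd.Series([0.0, 1.0, 1.0], index=abc_genes.index()),
            5,
        )
        rel = rd.RelativeExpressionMatrix(
            abc_genes,
            pd.DataFrame({"T": [0.0, 40.0, 60.0]}, index=abc_genes.index()),
            {"T": "t"},
        )
        with pytest.warns(rd.RibodergWarning, match="A"):
            dev = rd.percent_deviation_map(rel, ref)
        assert dev.loc["A"].isna().all() and not dev.loc["B"].isna().any()

    def test_normals_against_own_reference_have_zero_mean(self, rel_small):
        normals = rel_small.subset_samples(["N1", "N2"])
        ref = rd.normal_reference(normals)
        dev = rd.percent_deviation_map(normals, ref)
        assert np.allclose(dev.mean(axis=1), 0.0, atol=1e-9)


class TestOrderByReference:
    def make_profiles(self, ref_values):
        idx = pd.Index(["A", "B", "C"], name="gene")
        return [
            rd.GroupProfile("ctrl", pd.Series(ref_values, index=idx), 3),
            rd.GroupProfile("tumor", pd.Series([1.0, 2.0, 97.0], index=idx), 3),
        ]

    def test_forced_sort(self):
        order, reordered = rd.order_by_reference(self.make_profiles([10.0, 60.0, 30.0]), "ctrl")
        assert order == ["B", "C", "A"]
        assert list(reordered[1].mean_rel.index) == ["B", "C", "A"]

    def test_ties_break_alphabetically(self):
        order, _ = rd.order_by_reference(self.make_profiles([5.0, 90.0, 5.0]), "ctrl")
        assert order == ["B", "A", "C"]

    def test_missing_reference_group_rejected(self):
        with pytest.raises(ValueError, match="liver"):
            rd.order_by_reference(self.make_profiles([10.0, 60.0, 30.0]), "liver")
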