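"""The deregulation statistic set and its Model/Results wrapper."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import ribodereg as rd


class TestTranscriptPvalue:
    def test_at_the_mean_p_is_one(self):
        p, flag = rd.transcript_pvalue(10.0, 10.0, 2.0)
        assert p == 1.0 and not flag

    def test_critical_deviation_gives_p_005(self):
        p, _ = rd.transcript_pvalue(10.0 + 1.959964 * 2.0, 10.0, 2.0)
        assert abs(p - 0.05) < 1e-6

    def test_sigma_zero_is_flagged(self):
        p_eq, flag_eq = rd.transcript_pvalue(5.0, 5.0, 0.0)
        p_ne, flag_ne = rd.transcript_pvalue(6.0, 5.0, 0.0)
        assert (p_eq, flag_eq) == (1.0, True)
        assert (p_ne, flag_ne) == (0.0, True)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            rd.transcript_pvalue(1.0, 0.0, -1.0)

    @given(
        dev=st.floats(0, 50, allow_nan=False),
        extra=st.floats(0, 50, allow_nan=False),
        sigma=st.floats(0.01, 20),
    )
    def test_monotone_in_deviation_and_sign_symmetric(self, dev, extra, sigma):
        p_small, _ = rd.transcript_pvalue(10.0 + dev, 10.0, sigma)
        p_large, _ = rd.transcript_pvalue(10.0 + dev + extra, 10.0, sigma)
        p_neg, _ = rd.transcript_pvalue(10.0 - dev, 10.0, sigma)
        assert p_large <= p_small + 1e-15
        assert math.isclose(p_small, p_neg, rel_tol=1e-12)


class TestCountDeregulated:
    def test_strict_count(self):
        assert rd.count_deregulated([0.01, 0.2, 0.04], 0.05) == 2

    def test_p_equal_alpha_not_counted(self):
        assert rd.count_deregulated([0.05], 0.05) == 0

    def test_empty_list(self):
        assert rd.count_deregulated([], 0.05) == 0

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            rd.count_deregulated([1.5], 0.05)
        with pytest.raises(ValueError):
            rd.count_deregulated([0.1], 1.0)


class TestCohortBinomialTest:
    def test_k_is_floored_mean(self):
        result = rd.cohort_binomial_test([28, 29, 28], 77, 0.05)
        assert result.k == math.floor(result.mean_count) == 28

    def test_mean_zero_gives_full_tail(self):
        assert rd.cohort_binomial_test([0, 0], 77, 0.05).p_binomial == 1.0

    def test_matches_direct_pmf_summation(self):
        # independent oracle: direct sum of the 74 PMF terms at k = 4
        direct = sum(stats.binom.pmf(j, 77, 0.05) for j in range(4, 78))
        result = rd.cohort_binomial_test([4], 77, 0.05)
        assert math.isclose(result.p_binomial, direct, rel_tol=1e-12)

    def test_monotone_non_increasing_in_k(self):
        ps = [rd.cohort_binomial_test([k], 77, 0.05).p_binomial for k in range(78)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            rd.cohort_binomial_test([], 77, 0.05)

    def test_out_of_range_counts_rejected(self):
        with pytest.raises(ValueError):
            rd.cohort_binomial_test([78], 77, 0.05)


class TestDeregulationScore:
    def test_tumor_equal_to_mu_scores_zero(self, reference_small):
        profile = rd.deregulation_score(reference_small.mu, reference_small)
        assert profile.score == 0.0
        assert np.allclose(profile.deviation, 0.0)

    def test_forced_arithmetic(self, abc_genes):
        ref = rd.NormalReference(
            abc_genes,
            pd.Series([50.0, 30.0, 20.0], index=abc_genes.index()),
            pd.Series([1.0, 1.0, 1.0], index=abc_genes.index()),
            5,
        )
        tumor = pd.Series([40.0, 35.0, 25.0], index=abc_genes.index(), name="T1")
        profile = rd.deregulation_score(tumor, ref)
        assert profile.deviation.tolist() == [-10.0, 5.0, 5.0]
        assert profile.score == 20.0
        assert profile.sample_id == "T1"

    def test_score_invariant_under_joint_gene_permutation(self, plausible_reference):
        ref = plausible_reference
        rng = np.random.default_rng(1)
        tumor = ref.mu + rng.normal(0, 1, len(ref.mu))
        tumor = (100 * tumor.clip(lower=0) / tumor.clip(lower=0).sum())
        score = rd.deregulation_score(tumor.to_numpy(), ref).score
        perm = rng.permutation(len(ref.mu))
        genes_p = rd.GeneSet("p", tuple(np.array(ref.gene_set.genes)[perm]))
        ref_p = rd.NormalReference(
            genes_p,
            pd.Series(ref.mu.to_numpy()[perm], index=genes_p.index()),
            pd.Series(ref.sigma.to_numpy()[perm], index=genes_p.index()),
            ref.n_normals,
        )
        assert math.isclose(rd.deregulation_score(tumor.to_numpy()[perm], ref_p).score, score)

    def test_length_mismatch_rejected(self, reference_small):
        with pytest.raises(ValueError):
            rd.deregulation_score(np.array([1.0, 2.0]), reference_small)


class TestQuartileGroups:
    def test_eight_distinct_scores(self):
        labels = rd.quartile_groups({f"S{i}": float(i) for i in range(8)})
        counts = pd.Series(labels).value_counts()
        assert counts["upper"] == 2 and counts["lower"] == 2 and counts["middle"] == 4
        assert labels["S7"] == "upper" and labels["S0"] == "lower"

    def test_all_equal_resolved_by_sample_id(self):
        labels = rd.quartile_groups({s: 1.0 for s in ["D", "C", "B", "A"]})
        assert labels == {"A": "upper", "B": "middle", "C": "middle", "D": "lower"}

    def test_hundred_samples(self):
        labels = rd.quartile_groups({f"S{i:03d}": float(i) for i in range(100)})
        counts = pd.Series(labels).value_counts()
        assert counts["upper"] == 25 and counts["lower"] == 25

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            rd.quartile_groups({"A": 1.0, "B": 2.0, "C": 3.0})


class TestDeregulationModel:
    @pytest.fixture(scope="class")
    def fitted(self):
        cohort = rd.simulate_cohort(seed=7, n_tumors=60, n_normals=30)
        model = rd.DeregulationModel.from_expression(cohort.expression)
        return model.fit()

    def test_score_is_sum_of_absolute_deviations(self, fitted):
        assert np.allclose(fitted.scores, np.abs(fitted.deviations).sum(axis=0))

    def test_n_sig_counts_strictly_below_alpha(self, fitted):
        assert (fitted.n_sig == (fitted.pvalues < 0.05).sum(axis=0)).all()

    def test_pvalues_in_unit_interval(self, fitted):
        assert ((fitted.pvalues >= 0) & (fitted.pvalues <= 1)).all().all()

    def test_score_bounded_by_200(self, fitted):
        assert (fitted.scores <= 200.0).all()

    def test_quartile_labels_cover_all_tumors(self, fitted):
        assert set(fitted.quartiles.index) == set(fitted.scores.index)
        assert set(fitted.quartiles) <= {"upper", "lower", "middle"}

    def test_profiles_match_matrix_columns(self, fitted):
        profile = fitted.profiles[0]
        sample = profile.sample_id
        assert profile.n_sig == int(fitted.n_sig[sample])
        assert math.isclose(profile.score, float(fitted.scores[sample]))

    def test_summary_reports_cohort_test(self, fitted):
        text = fitted.summary()
        assert "cohort binomial P" in text and "tumors" in text

    def test_mismatched_gene_sets_rejected(self, fitted, reference_small):
        with pytest.raises(ValueError):
            rd.DeregulationModel(fitted.model.tumors, reference_small)
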