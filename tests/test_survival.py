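import copy

import numpy as np
import pytest
from hypothesis import given, strategies as st

import siscreen as ss
from siscreen.errors import ValidationError
from siscreen.survival import EXCLUDED, HIGH, LOW, NS, UNFAVORABLE


class TestFpkmToLog2Tpm:
    def test_hand_arithmetic(self):
        tpm = 2.0 ** ss.fpkm_to_log2tpm([1, 1, 2]) - 1
        assert tpm == pytest.approx([250_000, 250_000, 500_000])

    def test_single_gene_sample(self):
        out = ss.fpkm_to_log2tpm([5.0])
        assert out[0] == pytest.approx(np.log2(1e6 + 1))

    @given(scale=st.floats(0.001, 1000))
    def test_scale_invariance(self, scale):
        f = np.array([0.5, 3.0, 10.0, 0.0])
        assert np.allclose(ss.fpkm_to_log2tpm(f), ss.fpkm_to_log2tpm(f * scale))

    @given(
        f=st.lists(st.floats(0, 1e4), min_size=2, max_size=40).filter(
            lambda v: sum(v) > 0
        )
    )
    def test_tpm_sums_to_one_million(self, f):
        tpm = 2.0 ** ss.fpkm_to_log2tpm(f) - 1
        assert tpm.sum() == pytest.approx(1e6, rel=1e-6)

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValidationError, match="all-zero"):
            ss.fpkm_to_log2tpm([0.0, 0.0])

    def test_matrix_conversion_is_per_sample(self):
        import pandas as pd

        expr = pd.DataFrame({"S1": [1.0, 1.0, 2.0], "S2": [4.0, 4.0, 8.0]},
                            index=["A", "B", "C"])
        out = ss.fpkm_matrix_to_log2tpm(expr)
        assert np.allclose(out["S1"], out["S2"])  # scale invariance per column


class TestKMEstimate:
    def test_product_limit_hand_example(self):
        km = ss.km_estimate([1, 2, 3], [True, True, True])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(km.at_risk, [3, 2, 1])

    def test_all_censored_stays_at_one(self):
        km = ss.km_estimate([5, 8, 2], [False, False, False])
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0
        assert km.n_censored == 3

    def test_single_subject_event(self):
        km = ss.km_estimate([5.0], [True])
        assert km.survival_at(5.0) == 0.0
        assert km.survival_at(4.9) == 1.0

    def test_censored_at_event_time_remains_at_risk(self):
        # event and censoring tied at t=2: the censored subject counts in
        # the risk set, so S drops by 1/3 not 1/2
        km = ss.km_estimate([2, 2, 4], [True, False, True])
        assert km.survival_at(2.0) == pytest.approx(2 / 3)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 50)
        km = ss.km_estimate(t, np.ones(50, bool))
        for u in km.event_times:
            assert km.survival_at(u) == pytest.approx(np.mean(t > u))

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(9)
        t = np.ceil(rng.exponential(50, 80))
        e = rng.random(80) < 0.6
        km = ss.km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = [km.survival_at(u) for u in km.event_times]
        theirs = [float(kmf.predict(u)) for u in km.event_times]
        assert np.allclose(ours, theirs)

    def test_empty_and_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ss.km_estimate([], [])
        with pytest.raises(ValidationError):
            ss.km_estimate([0.0, 3.0], [True, True])


class TestLogrank:
    def test_matches_lifelines_oracle(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(2)
        for n in (12, 40, 150):
            t = np.ceil(rng.exponential(40, n))
            e = rng.random(n) < 0.7
            g = rng.random(n) < 0.5
            chi2, p = ss.logrank_test(g, t, e)
            ref = ll_logrank(t[g], t[~g], e[g], e[~g])
            assert chi2 == pytest.approx(ref.test_statistic)
            assert p == pytest.approx(ref.p_value)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        t = np.ceil(rng.exponential(40, 30))
        e = rng.random(30) < 0.7
        g = rng.random(30) < 0.4
        assert ss.logrank_test(g, t, e) == pytest.approx(ss.logrank_test(~g, t, e))

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError, match="non-empty"):
            ss.logrank_test([True, True], [1.0, 2.0], [True, True])

    def test_frozen_small_sample_permutation_fixture(self):
        """n=10 dataset where the chi-square p and the exact enumeration over
        all C(10,5) label assignments were both computed and agree closely."""
        t = np.array([21, 44, 109, 7, 13, 3, 32, 3, 52, 45], float)
        e = np.array([1, 0, 1, 1, 1, 1, 1, 1, 1, 0], bool)
        g = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], bool)
        _, p = ss.logrank_test(g, t, e)
        p_exact = ss.logrank_permutation_p(g, t, e)
        assert p == pytest.approx(0.6438, abs=1e-4)
        assert p_exact == pytest.approx(0.642857, abs=1e-6)
        assert abs(p - p_exact) < 0.02

    def test_asymptotic_tracks_permutation_on_random_small_samples(self):
        """Across random n=10 datasets the asymptotic p stays within ~0.07 of
        the exact permutation p (the permutation atom is 2/252)."""
        rng = np.random.default_rng(11)
        diffs = []
        for _ in range(10):
            t = np.ceil(rng.exponential(30, 10))
            e = rng.random(10) < 0.75
            g = np.zeros(10, bool)
            g[rng.choice(10, 5, replace=False)] = True
            if e.sum() < 3:
                continue
            _, p = ss.logrank_test(g, t, e)
            if np.isnan(p):
                continue
            diffs.append(abs(p - ss.logrank_permutation_p(g, t, e)))
        assert diffs and max(diffs) < 0.07

    def test_duplicating_both_groups_shrinks_p(self):
        rng = np.random.default_rng(6)
        t = np.ceil(rng.exponential(40, 40))
        e = rng.random(40) < 0.7
        g = np.arange(40) < 20
        chi2, p = ss.logrank_test(g, t, e)
        chi2d, pd_ = ss.logrank_test(
            np.tile(g, 2), np.tile(t, 2), np.tile(e, 2)
        )
        assert chi2d > chi2
        assert pd_ < p


class TestSplitByExpression:
    def test_quartile_1_to_8(self):
        labels = ss.split_by_expression(np.arange(1, 9), "QUARTILE")
        assert (labels == HIGH).sum() == 2
        assert (labels == LOW).sum() == 2
        assert (labels == EXCLUDED).sum() == 4

    def test_median_1_to_4(self):
        assert list(ss.split_by_expression([1, 2, 3, 4], "MEDIAN")) == [
            LOW, LOW, HIGH, HIGH,
        ]

    def test_all_equal_values_go_low_under_median(self):
        assert (ss.split_by_expression([5.0] * 6, "MEDIAN") == LOW).all()

    def test_minimum_n_enforced(self):
        with pytest.raises(ValidationError):
            ss.split_by_expression([1.0], "MEDIAN")
        with pytest.raises(ValidationError):
            ss.split_by_expression([1.0, 2.0, 3.0], "QUARTILE")


class TestScan48:
    def test_scan_has_48_cells_in_fixed_order(self):
        cohort = ss.generate_cohort(ss.CohortSimConfig(n_samples=80, seed=2))
        cells, call = ss.scan_48(cohort, "TARGET")
        assert len(cells) == 48
        assert (cells[0].endpoint, cells[0].split) == ("OS", "MEDIAN")
        assert cells[-1].endpoint == "DFS"
        assert not np.isnan(call.best_p)

    def test_single_stage_cohort_leaves_36_cells_missing(self):
        cohort = ss.generate_cohort(ss.CohortSimConfig(n_samples=80, seed=2))
        for s in cohort:
            s.stage = "II"
        cells, call = ss.scan_48(cohort, "TARGET")
        missing = [c for c in cells if np.isnan(c.p_value)]
        assert len(missing) >= 36
        assert all(c.stage_filter != "II" for c in missing)

    def test_best_p_is_minimum_over_valid_cells(self):
        cohort = ss.generate_cohort(ss.CohortSimConfig(n_samples=150, seed=8))
        cells, call = ss.scan_48(cohort, "TARGET")
        valid = [c.p_value for c in cells if not np.isnan(c.p_value)]
        assert call.best_p == min(valid)

    def test_planted_hazard_is_called_unfavorable(self):
        cohort = ss.generate_cohort(
            ss.CohortSimConfig(n_samples=300, hr_high_expression=3.0, seed=13)
        )
        _, call = ss.scan_48(cohort, "TARGET")
        assert call.call == UNFAVORABLE
        assert call.tier != NS

    def test_duplication_consistency_where_membership_preserved(self):
        """Duplicating every patient doubles the evidence: cells whose
        HIGH/LOW membership is unchanged keep their direction and get a
        smaller-or-equal p."""
        cohort = ss.generate_cohort(
            ss.CohortSimConfig(n_samples=120, hr_high_expression=1.8, seed=5)
        )
        cells, _ = ss.scan_48(cohort, "TARGET")
        dup = cohort + [copy.deepcopy(s) for s in cohort]
        cells2, _ = ss.scan_48(dup, "TARGET")
        compared = 0
        for a, b in zip(cells, cells2):
            if np.isnan(a.p_value) or np.isnan(b.p_value):
                continue
            if (b.n_high, b.n_low) != (2 * a.n_high, 2 * a.n_low):
                continue  # quantile boundary moved; membership changed
            compared += 1
            assert b.p_value <= a.p_value + 1e-9
            if a.direction != 0:
                assert b.direction == a.direction
        assert compared >= 24

    def test_missing_gene_is_error(self):
        cohort = ss.generate_cohort(ss.CohortSimConfig(n_samples=20, seed=1))
        with pytest.raises(ValidationError, match="NOSUCH"):
            ss.scan_48(cohort, "NOSUCH")


class TestMutationStratifiedScan:
    def test_empty_geneset_is_error(self):
        cohort = ss.generate_cohort(ss.CohortSimConfig(n_samples=20, seed=1))
        with pytest.raises(ValidationError, match="empty"):
            ss.mutation_stratified_scan(cohort, "TARGET", [])

    def test_geneset_matching_no_sample_reports_zero_subset(self):
        cohort = ss.generate_cohort(ss.CohortSimConfig(n_samples=30, seed=1))
        with pytest.raises(ValidationError, match="subset size 0"):
            ss.mutation_stratified_scan(cohort, "TARGET", ["NOT_A_MUTATION"])

    def test_geneset_of_all_mutated_genes_selects_all_carriers(self):
        cohort = ss.generate_cohort(ss.CohortSimConfig(n_samples=60, seed=4))
        all_muts = sorted({g for s in cohort for g in s.mutations})
        n_carriers = sum(1 for s in cohort if s.mutations)
        _, call = ss.mutation_stratified_scan(cohort, "TARGET", all_muts)
        assert call.n_samples == n_carriers


class TestOncoprintMatrix:
    def _cohort(self):
        cohort = ss.generate_cohort(ss.CohortSimConfig(n_samples=3, seed=1))
        cohort[0].mutations = {"KRAS"}
        cohort[1].mutations = {"KRAS", "TP53"}
        cohort[2].mutations = set()
        return cohort

    def test_hand_checked_matrix(self):
        mat, freqs, cooc = ss.oncoprint_matrix(self._cohort(), ["KRAS", "TP53"])
        assert mat.values.tolist() == [[1, 0], [1, 1], [0, 0]]
        assert freqs.tolist() == [2, 1]
        assert cooc.loc["KRAS", "TP53"] == 1

    def test_no_mutations_gives_zero_matrix(self):
        cohort = self._cohort()
        for s in cohort:
            s.mutations = set()
        mat, freqs, _ = ss.oncoprint_matrix(cohort, ["KRAS", "TP53"])
        assert not mat.values.any()
        assert freqs.sum() == 0

    def test_column_sums_equal_carrier_counts(self):
        cohort = ss.generate_cohort(ss.CohortSimConfig(n_samples=50, seed=6))
        genes = sorted({g for s in cohort for g in s.mutations})
        mat, freqs, _ = ss.oncoprint_matrix(cohort, genes)
        for g in genes:
            assert freqs[g] == sum(1 for s in cohort if g in s.mutations)
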