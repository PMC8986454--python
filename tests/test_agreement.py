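"""Agreement statistics: differences, ranges, tests, prevalence tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from scgcti.agreement import (ReferenceEntry, count_within_range,
                              ef_band, f_test_variances, g_test_independence,
                              group_stats, load_cohort_fixture, load_reference,
                              load_study_differences, patient_differences,
                              prevalence_table, reference_range, welch_test)


class TestPatientDifferences:
    def test_repeated_measures_averaged_with_sign_convention(self):
        d = patient_differences({"AO": [78.0, 82.0]}, {"AO": 90.0})
        assert d["AO"] == pytest.approx(-10.0)

    def test_measure_equal_to_fp_gives_zero(self):
        assert patient_differences({"MC": [35.0]}, {"MC": 35.0})["MC"] == 0.0

    def test_global_times_referred_to_preceding_r(self):
        r = np.array([0.0, 900.0, 1800.0])
        d = patient_differences({"AO": [980.0, 1878.0]}, {"AO": 82.0}, r_times=r)
        assert d["AO"] == pytest.approx(np.mean([80.0 - 82.0, 78.0 - 82.0]))

    def test_missing_fp_or_measures_omitted(self):
        d = patient_differences({"AO": [], "AC": [300.0]}, {"AO": 80.0, "AC": None})
        assert d == {}


class TestGroupStats:
    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"MC": rng.normal(0, 10, 25)})
        gs = group_stats(df)
        x = df["MC"].to_numpy()
        mean = x.sum() / len(x)
        sd = np.sqrt(((x - mean) ** 2).sum() / (len(x) - 1))
        assert gs.loc["MC", "mean"] == pytest.approx(mean, rel=1e-9)
        assert gs.loc["MC", "sd"] == pytest.approx(sd, rel=1e-9)

    def test_published_per_patient_columns_reproduce_printed_rows(self):
        gs = group_stats(load_study_differences())
        printed = {"MC": (-17.1, 26.2), "AO": (-1.3, 18.3),
                   "AC": (-13.2, 17.8), "MO": (-5.4, 28.3)}
        for ev, (m, s) in printed.items():
            assert abs(gs.loc[ev, "mean"] - m) <= 0.05 + 1e-9
            assert abs(gs.loc[ev, "sd"] - s) <= 0.05 + 1e-9

    def test_identical_values_have_zero_sd(self):
        gs = group_stats(pd.DataFrame({"AO": [5.0] * 4}))
        assert gs.loc["AO", "sd"] == 0.0


class TestReferenceRange:
    def test_exact_mode_is_mean_pm_196_sd(self):
        lo, hi = reference_range(ReferenceEntry(4.0, 11.0, 41, 22.0), "exact")
        assert (lo, hi) == pytest.approx((-17.56, 25.56))

    def test_printed_mode_uses_rounded_half_width(self):
        assert reference_range(ReferenceEntry(4.0, 11.0, 41, 22.0),
                               "printed") == (-18.0, 26.0)

    def test_zero_sd_gives_degenerate_range(self):
        lo, hi = reference_range(ReferenceEntry(4.0, 0.0, 10, 0.0), "exact")
        assert lo == hi == 4.0

    def test_counts_inclusive_at_bounds(self):
        t4 = load_study_differences()
        assert count_within_range(t4["MC"], (-18.0, 26.0)) == 10
        # AO holds a value exactly on the lower bound; inclusive counts it
        assert count_within_range(t4["AO"], (-25.0, 19.0)) == 18
        assert count_within_range(t4["AO"], (-25.0, 19.0), inclusive=False) == 17

    def test_empty_list_counts_zero(self):
        assert count_within_range([], (-1.0, 1.0)) == 0

    def test_within_plus_outside_is_total(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 20, 50)
        inside = count_within_range(v, (-10.0, 10.0))
        outside = np.sum((v < -10.0) | (v > 10.0))
        assert inside + outside == 50


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        r = welch_test(5.0, 2.0, 10, 5.0, 2.0, 10)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_matches_scipy_summary_stat_route(self):
        r = welch_test(-17.05, 26.23, 20, 4.0, 11.0, 41)
        t, p = sstats.ttest_ind_from_stats(-17.05, 26.23, 20, 4.0, 11.0, 41,
                                           equal_var=False)
        assert r.statistic == pytest.approx(t)
        assert r.p_value == pytest.approx(p)

    def test_group_swap_invariance(self):
        a = welch_test(1.0, 3.0, 12, -2.0, 5.0, 30)
        b = welch_test(-2.0, 5.0, 30, 1.0, 3.0, 12)
        assert a.p_value == pytest.approx(b.p_value)

    def test_precondition_validation(self):
        with pytest.raises(ValueError):
            welch_test(0.0, 1.0, 1, 0.0, 1.0, 10)
        with pytest.raises(ValueError):
            welch_test(0.0, 0.0, 5, 0.0, 1.0, 10)


class TestFTest:
    def test_equal_sds_give_f1(self):
        r = f_test_variances(3.0, 15, 3.0, 15)
        assert r.statistic == 1.0 and r.p_value == 1.0
        # with unequal group sizes the doubled upper tail is < 1 at F = 1
        r = f_test_variances(3.0, 10, 3.0, 20)
        assert r.statistic == 1.0 and r.p_value > 0.9

    def test_group_swap_invariance(self):
        a = f_test_variances(26.2, 20, 11.0, 41)
        b = f_test_variances(11.0, 41, 26.2, 20)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.df == b.df    # larger-variance group listed first

    def test_monte_carlo_null_calibration(self):
        """Under equal variances the two-sided p is ~Uniform(0,1)."""
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(400):
            x = rng.normal(0, 1, 15)
            y = rng.normal(0, 1, 20)
            ps.append(f_test_variances(x.std(ddof=1), 15, y.std(ddof=1), 20)
                      .p_value)
        assert sstats.kstest(ps, "uniform").pvalue > 0.01


class TestGTest:
    def test_matches_scipy_log_likelihood_route(self):
        obs = [[26, 8], [27, 22]]
        r = g_test_independence(obs)
        g, p, dof, _ = sstats.chi2_contingency(obs, correction=False,
                                               lambda_="log-likelihood")
        assert r.statistic == pytest.approx(g)
        assert r.p_value == pytest.approx(p)
        assert r.df == dof

    def test_identical_row_proportions_give_g0(self):
        r = g_test_independence([[10, 20], [20, 40]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_symmetric_table_gives_g0(self):
        assert g_test_independence([[10, 10], [10, 10]]).statistic == \
            pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            g_test_independence([[0, 0], [5, 3]])

    def test_williams_correction_shrinks_g(self):
        plain = g_test_independence([[26, 8], [27, 22]])
        corr = g_test_independence([[26, 8], [27, 22]], williams=True)
        assert corr.statistic < plain.statistic


class TestPrevalence:
    def test_fixture_reproduces_diagnosis_strata(self):
        tab = prevalence_table(load_cohort_fixture(), "diagnosis")
        rows = {r.stratum: (r.n_patients, r.n_traditional, r.prevalence_pct)
                for r in tab.itertuples()}
        assert rows["MI"] == (34, 26, 76)
        assert rows["HF"] == (49, 27, 55)
        assert rows["TX"] == (7, 3, 43)

    def test_fixture_reproduces_ef_strata(self):
        tab = prevalence_table(load_cohort_fixture(), "ef")
        rows = {r.stratum: (r.n_patients, r.n_traditional)
                for r in tab.itertuples()}
        assert rows[">50%"] == (13, 8)
        assert rows["40-50%"] == (21, 14)
        assert rows["<40%"] == (52, 31)
        assert "unavailable" in rows

    def test_empty_cohort_gives_empty_table(self):
        assert len(prevalence_table(pd.DataFrame(), "diagnosis")) == 0

    def test_ef_banding(self):
        assert ef_band(55.0) == ">50%"
        assert ef_band(50.0) == "40-50%"
        assert ef_band(40.0) == "40-50%"
        assert ef_band(39.9) == "<40%"
        assert ef_band(None) is None

    def test_reference_constants_as_packaged(self):
        ref = load_reference()
        assert (ref["MC"].mean, ref["MC"].sd, ref["MC"].n) == (4, 11, 41)
        assert (ref["MO"].mean, ref["MO"].sd, ref["MO"].n) == (-7, 19, 39)
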