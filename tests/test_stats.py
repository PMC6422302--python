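"""Two-group statistics, q-values, correlations, demographics battery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import metabddx as m
from metabddx.datamodel import AnalysisConfig, subjects_to_frame
from metabddx.stats import (
    caps_correlation,
    chi_square_2x2,
    cohens_d,
    cohens_d_from_summary,
    demographics_table,
    differential_analysis,
    fold_change,
    pooled_t_from_summary,
    pooled_t_test,
    significance_label,
    storey_pi0,
    storey_qvalues,
)


class TestPooledT:
    def test_published_caps_summary_statistic(self):
        t, p = pooled_t_from_summary(51, 2.90, 4.24, 52, 68.02, 16.80)
        assert abs(t) == pytest.approx(26.85, abs=0.005)
        assert p < 1e-40

    def test_published_glucose_summary_statistic(self):
        t, _ = pooled_t_from_summary(51, 79.94, 13.76, 52, 91.42, 23.57)
        assert abs(t) == pytest.approx(3.01, abs=0.005)

    def test_identical_samples_give_zero_t_unit_p(self):
        assert pooled_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == (0.0, 1.0)

    def test_zero_variance_unequal_means_is_error(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            pooled_t_test([1.0, 1.0], [2.0, 2.0])

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=30), rng.normal(0.5, 1.2, size=25)
        t, p = pooled_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert (t, p) == (ref.statistic, ref.pvalue)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_summary_form_agrees_with_vector_form(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(1.0, 0.5, size=rng.integers(3, 40))
        b = rng.normal(1.2, 0.7, size=rng.integers(3, 40))
        tv, pv = pooled_t_test(a, b)
        ts, ps = pooled_t_from_summary(
            a.size, a.mean(), a.std(ddof=1), b.size, b.mean(), b.std(ddof=1)
        )
        assert tv == pytest.approx(ts, abs=1e-10)
        assert pv == pytest.approx(ps, abs=1e-10)

    def test_welch_flag_changes_unequal_variance_result(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.2, 40)
        b = rng.normal(0.3, 2.0, 12)
        assert pooled_t_test(a, b) != pooled_t_test(a, b, welch=True)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError, match=">= 2"):
            pooled_t_test([1.0], [1.0, 2.0])


class TestEffectSizes:
    def test_equal_means_give_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_half_sd_shift_gives_unit_d(self):
        assert cohens_d_from_summary(20, 1.0, 0.5, 20, 1.5, 0.5) == pytest.approx(1.0)

    def test_published_summary_oracle(self):
        # raw-scale glutathione-pathway summaries; formula oracle value
        d = cohens_d_from_summary(51, 0.943, 0.149, 52, 1.073, 0.187)
        assert d == pytest.approx(0.7681, abs=1e-3)

    def test_zero_pooled_sd_is_error(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d_from_summary(5, 1.0, 0.0, 5, 2.0, 0.0)

    def test_fold_change_published_values(self):
        assert fold_change(0.937, 1.239) == pytest.approx(1.322, abs=0.0015)
        assert fold_change(1.331, 0.829) == pytest.approx(0.623, abs=0.0015)
        assert fold_change(1.0, 1.0) == 1.0
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)


class TestChiSquare:
    def test_smoking_counts_reproduce_uncorrected_statistic(self):
        stat, p = chi_square_2x2([[48, 3], [41, 11]])
        assert stat == pytest.approx(5.11, abs=0.01)
        assert p == pytest.approx(0.02, abs=0.005)

    def test_independent_table(self):
        stat, p = chi_square_2x2([[5, 5], [5, 5]])
        assert (stat, p) == (0.0, 1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_continuity_correction_not_default(self):
        _, p_default = chi_square_2x2([[48, 3], [41, 11]])
        _, p_yates = chi_square_2x2([[48, 3], [41, 11]], correction=True)
        assert p_default < 0.03 < p_yates


class TestStoreyQValues:
    def test_single_test_is_its_own_q(self):
        assert storey_qvalues([0.05]) == pytest.approx([0.05])

    def test_step_up_oracle(self):
        q = storey_qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equals_benjamini_hochberg_when_pi0_is_one(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.random(rng.integers(5, 200))
            q = storey_qvalues(p, pi0=1.0)
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, bh, atol=1e-13)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=60))
    def test_monotone_nondecreasing_in_p(self, ps):
        p = np.asarray(ps)
        q = storey_qvalues(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all((q >= 0) & (q <= 1))

    def test_pi0_estimated_near_one_under_global_null(self):
        rng = np.random.default_rng(2)
        p = rng.random(2000)
        pi0 = storey_pi0(p, AnalysisConfig().qvalue_lambda)
        assert 0.85 <= pi0 <= 1.0

    def test_pi0_shrinks_with_signal(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.random(500), rng.beta(0.1, 10, size=500)])
        pi0 = storey_pi0(p, AnalysisConfig().qvalue_lambda)
        assert pi0 < 0.8

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])


class TestSignificanceLabels:
    @pytest.mark.parametrize(
        "p,label",
        [(0.049, "significant"), (0.05, "significant"), (0.051, "trend"),
         (0.1, "trend"), (0.11, "ns")],
    )
    def test_band_edges(self, p, label):
        assert significance_label(p, AnalysisConfig()) == label


class TestDifferentialAnalysis:
    def test_reported_scales_are_mixed(self, default_cohort):
        """Means/fold on the raw scaled-intensity scale, t/d on Blom scores."""
        matrix, subjects = default_cohort
        scaled, blom = m.prepare_cohort(matrix)
        res = differential_analysis(scaled, blom, subjects)
        grp = subjects.loc[scaled.subject_ids, "group"] == "ptsd_pos"
        raw = scaled.values
        assert res.loc["lactate", "mean_ptsd"] == pytest.approx(
            raw.loc[grp.to_numpy(), "lactate"].mean()
        )
        t, p = pooled_t_test(
            blom.loc[grp.to_numpy(), "lactate"], blom.loc[~grp.to_numpy(), "lactate"]
        )
        assert res.loc["lactate", "t_stat"] == pytest.approx(t, abs=1e-10)
        assert res.loc["lactate", "p_value"] == pytest.approx(p, abs=1e-12)
        assert res.loc["lactate", "fold_change"] == pytest.approx(
            res.loc["lactate", "mean_ptsd"] / res.loc["lactate", "mean_control"]
        )

    def test_constant_analyte_reports_null_result(self, default_cohort):
        matrix, subjects = default_cohort
        frame = matrix.values.copy()
        frame["flatline"] = 1.0
        from metabddx.datamodel import MetaboliteMatrix

        scaled, blom = m.prepare_cohort(MetaboliteMatrix(frame), ratio_defs=None)
        res = differential_analysis(scaled, blom, subjects)
        assert res.loc["flatline", "t_stat"] == 0.0
        assert res.loc["flatline", "p_value"] == 1.0

    def test_strong_effects_reach_significance(self, discovery_battery, expected_directions):
        """Analytes configured at the largest published effect size are
        detected in >=90% of 200 cohorts."""
        _, frame = discovery_battery
        lactate = frame[frame["analyte"] == "lactate"]
        hit = (lactate["p_value"] <= 0.05) & (
            lactate["direction"] == expected_directions["lactate"]
        )
        assert hit.mean() >= 0.90


class TestCapsCorrelation:
    def _blom_and_subjects(self):
        matrix, records = m.generate(m.default_spec(), 13)
        subjects = subjects_to_frame(records)
        _, blom = m.prepare_cohort(matrix)
        return blom, subjects

    def test_analyte_equal_to_caps_has_unit_correlation(self):
        blom, subjects = self._blom_and_subjects()
        blom = blom.copy()
        blom["caps_clone"] = subjects.loc[blom.index, "caps_current"].to_numpy()
        out = caps_correlation(blom, subjects, analytes=["caps_clone"])
        assert out.loc["caps_clone", "r"] == pytest.approx(1.0)

    def test_constant_analyte_flagged_not_computable(self):
        blom, subjects = self._blom_and_subjects()
        blom = blom.copy()
        blom["flat"] = 0.0
        out = caps_correlation(blom, subjects, analytes=["flat"])
        assert not out.loc["flat", "computable"]

    def test_independent_analytes_have_near_zero_r_at_large_n(self):
        rng = np.random.default_rng(21)
        n = 5000
        subjects = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "cohort": "discovery",
                "group": "ptsd_pos",
                "caps_current": rng.normal(68, 17, n).clip(0),
            }
        ).set_index("subject_id", drop=False)
        blom = pd.DataFrame(
            {"x": rng.normal(size=n)}, index=subjects.index
        )
        out = caps_correlation(blom, subjects)
        assert abs(out.loc["x", "r"]) < 0.05

    def test_too_few_cases_rejected(self):
        subjects = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "cohort": "discovery",
                "group": "ptsd_pos",
                "caps_current": [50.0, 60.0],
            }
        ).set_index("subject_id", drop=False)
        blom = pd.DataFrame({"x": [0.1, 0.2]}, index=subjects.index)
        with pytest.raises(ValueError, match=">= 3"):
            caps_correlation(blom, subjects)


class TestDemographics:
    def test_battery_reproduces_direct_tests(self, default_cohort):
        _, subjects = default_cohort
        table = demographics_table(subjects)
        # continuous: glucose row equals a direct pooled t on the vectors
        ptsd = subjects[subjects["group"] == "ptsd_pos"]["glucose"]
        ctrl = subjects[subjects["group"] == "ptsd_neg"]["glucose"]
        t, p = pooled_t_test(ptsd, ctrl)
        assert table.loc["glucose", "statistic"] == pytest.approx(abs(t))
        assert table.loc["glucose", "p_value"] == pytest.approx(p)
        # dichotomous: smoker row equals a direct uncorrected chi-square
        counts = pd.crosstab(subjects["group"], subjects["smoker"])
        stat, p2 = chi_square_2x2(counts.to_numpy())
        assert table.loc["smoker", "statistic"] == pytest.approx(stat)
        assert table.loc["smoker", "p_value"] == pytest.approx(p2)
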