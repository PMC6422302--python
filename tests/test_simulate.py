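"""Synthetic cohort generator: defaults, determinism, distributional
fidelity (moment matching, censoring, type-I calibration, recovery)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

import metabddx as m
from metabddx.datamodel import GROUP_PTSD, subjects_to_frame
from metabddx.simulate import AnalyteSpec, CohortSpec, truncnorm_params

COVARIATE_MODEL = {
    "bmi": (28.0, 4.0, 30.0, 5.0),
    "hba1c": (5.4, 0.4, 5.4, 0.9),
    "glucose": (80.0, 14.0, 91.0, 24.0),
    "waist_hip": (0.89, 0.12, 0.91, 0.08),
}


def small_spec(**overrides) -> CohortSpec:
    base = dict(
        cohort="discovery",
        n_control=40,
        n_ptsd=40,
        analytes=[
            AnalyteSpec("up", 1.0, 0.3, 1.3, 0.35, lod_quantile=0.0),
            AnalyteSpec("flat", 1.0, 0.3, 1.0, 0.3, lod_quantile=0.0),
        ],
        covariate_model=dict(COVARIATE_MODEL),
        med_prevalence={"statins": (0.05, 0.1)},
    )
    base.update(overrides)
    return CohortSpec(**base)


class TestDefaultSpec:
    def test_lactate_uses_published_discovery_summaries(self):
        spec = m.default_spec()
        lactate = {a.name: a for a in spec.analytes}["lactate"]
        assert (lactate.control_mean, lactate.control_sd) == (0.937, 0.283)
        assert (lactate.ptsd_mean, lactate.ptsd_sd) == (1.239, 0.341)

    def test_cohort_sizes(self):
        assert (m.default_spec().n_control, m.default_spec().n_ptsd) == (51, 52)
        test = m.default_spec("test")
        assert (test.n_control, test.n_ptsd) == (31, 31)

    def test_null_analytes_present_and_truly_null(self):
        spec = m.default_spec()
        nulls = [a for a in spec.analytes if a.name.startswith("null_")]
        assert len(nulls) >= 20
        assert all(a.ptsd_mean == a.control_mean for a in nulls)
        assert all(a.is_null for a in nulls)

    def test_ratio_components_available(self):
        names = {a.name for a in m.default_spec().analytes}
        assert {"pyruvate", "lactate", "citrate", "arginine", "ornithine", "citrulline"} <= names


class TestTruncnormMomentMatching:
    @pytest.mark.parametrize(
        "mean,sd",
        [(1.056, 0.736), (0.781, 0.327), (1.033, 0.639), (0.937, 0.283), (2.0, 0.5)],
    )
    def test_truncated_moments_equal_request(self, mean, sd):
        mu, sigma, alpha = truncnorm_params(mean, sd)
        dist = truncnorm(a=alpha, b=np.inf, loc=mu, scale=sigma)
        assert dist.mean() == pytest.approx(mean, abs=1e-9)
        assert dist.std() == pytest.approx(sd, abs=1e-9)

    def test_low_ratio_falls_back_to_parent_parameters(self):
        # mean/sd < 1 is unattainable for a zero-truncated normal
        mu, sigma, _ = truncnorm_params(2.9, 4.24)
        assert (mu, sigma) == (2.9, 4.24)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            truncnorm_params(-1.0, 1.0)


class TestGenerate:
    def test_fixed_seed_bit_identical(self):
        spec = m.default_spec()
        m1, r1 = m.generate(spec, 3)
        m2, r2 = m.generate(spec, 3)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(m1.mask, m2.mask)
        assert r1 == r2

    def test_different_seeds_differ(self):
        spec = small_spec()
        m1, _ = m.generate(spec, 1)
        m2, _ = m.generate(spec, 2)
        assert not m1.values.equals(m2.values)

    def test_zero_lod_means_no_censoring(self):
        matrix, _ = m.generate(small_spec(), 0)
        assert not matrix.mask.to_numpy().any()

    def test_group_labels_and_sizes(self):
        matrix, records = m.generate(small_spec(n_control=10, n_ptsd=12), 0)
        frame = subjects_to_frame(records)
        assert (frame["group"] == GROUP_PTSD).sum() == 12
        assert matrix.n_subjects == 22

    def test_large_sample_means_match_spec(self):
        """Law of large numbers at n=5000: each control sample mean within
        3*SD/sqrt(n) of its configured mean (binomial allowance: <=1 of the
        43 analytes may sit outside a 3-sigma band)."""
        ref = m.default_spec()
        spec = small_spec(
            n_control=5000,
            n_ptsd=10,
            analytes=[
                AnalyteSpec(a.name, a.control_mean, a.control_sd,
                            a.ptsd_mean, a.ptsd_sd, lod_quantile=0.0)
                for a in ref.analytes
            ],
        )
        matrix, _ = m.generate(spec, 42)
        fails = 0
        for a in spec.analytes:
            x = matrix.values[a.name].to_numpy()[:5000]
            if abs(x.mean() - a.control_mean) > 3 * a.control_sd / np.sqrt(5000):
                fails += 1
        assert fails <= 1

    def test_censoring_rate_tracks_lod_quantile(self):
        spec = small_spec(
            n_control=2000,
            n_ptsd=10,
            analytes=[AnalyteSpec("x", 1.0, 0.3, 1.0, 0.3, lod_quantile=0.2)],
        )
        matrix, _ = m.generate(spec, 5)
        rate = matrix.mask["x"].to_numpy()[:2000].mean()
        assert rate == pytest.approx(0.2, abs=0.03)

    def test_latent_factor_correlates_analytes_but_keeps_marginals(self):
        spec = small_spec(
            n_control=3000,
            n_ptsd=10,
            analytes=[
                AnalyteSpec("x", 1.0, 0.3, 1.0, 0.3, lod_quantile=0.0),
                AnalyteSpec("y", 1.0, 0.3, 1.0, 0.3, lod_quantile=0.0),
            ],
            latent_loading=0.6,
        )
        matrix, _ = m.generate(spec, 9)
        x = matrix.values["x"].to_numpy()[:3000]
        y = matrix.values["y"].to_numpy()[:3000]
        assert np.corrcoef(x, y)[0, 1] > 0.2
        assert x.mean() == pytest.approx(1.0, abs=3 * 0.3 / np.sqrt(3000))

    def test_leakage_adds_covariate_signal(self):
        spec = small_spec(leakage={"flat": ("glucose", 0.1)})
        matrix, records = m.generate(spec, 4)
        frame = subjects_to_frame(records)
        r = np.corrcoef(matrix.values["flat"], frame["glucose"])[0, 1]
        assert r > 0.8

    def test_mdd_only_in_cases_by_default(self):
        _, records = m.generate(m.default_spec(), 0)
        frame = subjects_to_frame(records)
        assert frame.loc[frame["group"] != GROUP_PTSD, "mdd"].sum() == 0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            small_spec(n_control=1)
        with pytest.raises(ValueError):
            AnalyteSpec("bad", 1.0, 0.3, 1.0, 0.3, lod_quantile=1.0)
        with pytest.raises(ValueError):
            small_spec(med_prevalence={"statins": (0.5, 1.5)})
        with pytest.raises(ValueError):
            small_spec(leakage={"nope": ("glucose", 0.1)})


class TestCalibration:
    def test_type_one_error_of_null_analytes(self, discovery_battery):
        """Across 200 cohorts the unadjusted p<0.05 rate over the 20 null
        analytes stays within the spec band [0.03, 0.07]."""
        _, frame = discovery_battery
        nulls = frame[frame["analyte"].str.startswith("null_")]
        rate = (nulls["p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_fold_change_parameter_recovery(self):
        """Mean recovered fold change within 2% of the configured
        case/control mean ratio for every non-null analyte (1000 seeds so
        the check is decisive for the high-CV analytes)."""
        spec = m.default_spec()
        targets = {
            a.name: a.ptsd_mean / a.control_mean
            for a in spec.analytes
            if not a.is_null
        }
        sums = dict.fromkeys(targets, 0.0)
        n_seeds = 1000
        for seed in range(n_seeds):
            matrix, records = m.generate(spec, seed)
            scaled, _ = m.prepare_cohort(matrix, ratio_defs=None)
            grp = np.array([r.group for r in records]) == GROUP_PTSD
            mc = scaled.values.loc[~grp].mean()
            mp = scaled.values.loc[grp].mean()
            for name in targets:
                sums[name] += mp[name] / mc[name]
        for name, target in targets.items():
            assert sums[name] / n_seeds == pytest.approx(target, rel=0.02), name

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = small_spec(leakage={"flat": ("glucose", 0.05)})
        m.simulate.spec_to_yaml(spec, tmp_path / "spec.yaml")
        back = m.simulate.spec_from_yaml(tmp_path / "spec.yaml")
        assert back == spec
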