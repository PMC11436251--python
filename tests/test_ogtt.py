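import numpy as np
import pandas as pd
import pytest

from glucosens import ogtt
from glucosens.ogtt import (
    CohortSpec,
    SubjectProfile,
    cohort_summary,
    compare_sensitivities,
    estimate_sensitivity,
    glucose_curve,
    make_cohort,
    synth_series,
)


class TestGlucoseCurve:
    def test_starts_at_fasting_baseline(self):
        p = SubjectProfile()
        assert glucose_curve(p, [0.0])[0] == p.baseline_glucose

    def test_peak_location_and_height(self):
        p = SubjectProfile(time_to_peak=40.0, decay_time=45.0)
        t = np.linspace(0, 200, 40_001)
        cg = glucose_curve(p, t)
        assert t[np.argmax(cg)] == pytest.approx(40.0, abs=0.01)
        assert cg.max() == pytest.approx(p.baseline_glucose + p.excursion_amplitude, rel=1e-9)

    def test_zero_amplitude_is_flat(self):
        p = SubjectProfile(excursion_amplitude=0.0)
        assert np.ptp(glucose_curve(p, np.arange(0, 121, 10))) == 0.0

    def test_strictly_positive(self):
        p = SubjectProfile(baseline_glucose=3.5, excursion_amplitude=6.0)
        assert np.all(glucose_curve(p, np.arange(0, 300, 5)) > 0)


class TestSynthSeries:
    def test_noise_free_series_is_exactly_affine(self):
        p = SubjectProfile(noise_sd=0.0, drift_rate=0.0)
        s = synth_series(p)
        est = estimate_sensitivity(s, 1314.0)
        assert est.dAD_dCg == pytest.approx(p.true_sensitivity[1314.0], rel=1e-9)
        assert abs(est.pearson_r) == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        p = SubjectProfile(seed=77)
        s1, s2 = synth_series(p), synth_series(p)
        for wl in s1.a_d:
            assert np.array_equal(s1.a_d[wl], s2.a_d[wl])

    def test_default_sampling_grid(self):
        s = synth_series(SubjectProfile())
        assert len(s.times) == 13
        assert np.all(np.diff(s.times) == 10.0)

    def test_drift_invariance_of_slope(self):
        # zero drift leaves the slope untouched; nonzero drift perturbs it
        p0 = SubjectProfile(noise_sd=0.0, drift_rate=0.0)
        p1 = SubjectProfile(noise_sd=0.0, drift_rate=5e-6)
        e0 = estimate_sensitivity(synth_series(p0), 1314.0)
        e1 = estimate_sensitivity(synth_series(p1), 1314.0)
        assert e0.dAD_dCg == pytest.approx(p0.true_sensitivity[1314.0], rel=1e-9)
        assert e1.dAD_dCg != pytest.approx(p0.true_sensitivity[1314.0], rel=1e-9)


class TestEstimateSensitivity:
    def test_constant_glucose_rejected(self):
        p = SubjectProfile(excursion_amplitude=0.0)
        with pytest.raises(ValueError, match="constant"):
            estimate_sensitivity(synth_series(p), 1314.0)

    def test_too_few_points_rejected(self):
        p = SubjectProfile()
        with pytest.raises(ValueError):
            estimate_sensitivity(synth_series(p, times=[0.0, 10.0]), 1314.0)

    def test_bias_shrinks_with_noise_and_points(self):
        # estimator consistency on a (noise, n_points) grid
        truth = SubjectProfile().true_sensitivity[1314.0]
        biases = []
        for noise in (3e-4, 3e-5, 0.0):
            est = []
            for seed in range(150):
                p = SubjectProfile(noise_sd=noise, seed=seed)
                est.append(estimate_sensitivity(synth_series(p), 1314.0).dAD_dCg)
            biases.append(abs(np.mean(est) - truth))
        assert biases[2] < 1e-12
        assert biases[1] < biases[0] + 1e-12

        dense = [
            estimate_sensitivity(
                synth_series(SubjectProfile(noise_sd=3e-4, seed=s), times=np.arange(0, 121, 2.0)),
                1314.0,
            ).dAD_dCg
            for s in range(150)
        ]
        sparse = [
            estimate_sensitivity(synth_series(SubjectProfile(noise_sd=3e-4, seed=s)), 1314.0).dAD_dCg
            for s in range(150)
        ]
        assert np.std(dense) < np.std(sparse)

    def test_null_sensitivity_confidence_coverage(self):
        # true slope 0: the 95% CI should cover 0 in about 95% of replicates
        from scipy import stats as sps

        cover = 0
        n_rep = 300
        rs = []
        for seed in range(n_rep):
            p = SubjectProfile(true_sensitivity={1314.0: 0.0}, seed=seed)
            s = synth_series(p)
            est = estimate_sensitivity(s, 1314.0)
            tcrit = sps.t.ppf(0.975, est.n_points - 2)
            if abs(est.dAD_dCg) <= tcrit * est.stderr:
                cover += 1
            rs.append(abs(est.pearson_r))
        assert 0.90 <= cover / n_rep <= 0.99
        assert np.mean(rs) < 0.4


class TestCohort:
    def test_default_group_split(self):
        profiles = make_cohort(CohortSpec(), seed=1)
        groups = pd.Series([p.group for p in profiles]).value_counts()
        assert groups["elderly-male"] == 6
        assert groups["elderly-female"] == 7
        assert groups["young-male"] == 6
        assert groups["young-female"] == 6
        assert len(profiles) == 25

    def test_group_multiplier_ordering_recovered(self):
        mult = {"elderly-male": 1.0, "elderly-female": 1.4, "young-male": 1.0, "young-female": 1.4}
        spec = CohortSpec(
            group_sizes={g: 60 for g in mult},
            group_multipliers=mult,
            noise_sd=1e-5,
        )
        est = ogtt.cohort_estimates(make_cohort(spec, seed=5), wavelengths=[1314.0])
        means = est.groupby("group")["dAD_dCg"].mean()
        assert abs(means["elderly-female"]) > abs(means["elderly-male"])
        assert abs(means["young-female"]) > abs(means["young-male"])

    def test_parameter_recovery_within_two_standard_errors(self):
        # >= 200 synthetic subjects: cohort-mean slope close to truth
        spec = CohortSpec(group_sizes={g: 60 for g in ogtt.GROUPS})
        est = ogtt.cohort_estimates(make_cohort(spec, seed=9), wavelengths=[1314.0])
        truth = spec.mean_sensitivity[1314.0]
        mean = est["dAD_dCg"].mean()
        se = est["dAD_dCg"].std(ddof=1) / np.sqrt(len(est))
        assert abs(mean - truth) <= 2.0 * se

    def test_correlation_decreases_with_noise(self):
        means = []
        for noise in (1e-4, 3e-4, 9e-4):
            spec = CohortSpec(group_sizes={g: 60 for g in ogtt.GROUPS}, noise_sd=noise)
            est = ogtt.cohort_estimates(make_cohort(spec, seed=3), wavelengths=[1314.0])
            means.append(np.abs(est["pearson_r"]).mean())
        assert means[0] > means[1] > means[2]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(group_sizes={g: 0 for g in ogtt.GROUPS})


class TestSummaryAndComparison:
    def test_identical_subjects_have_zero_dispersion(self):
        rows = [
            {"subject_id": f"S{i}", "group": "young-male", "wavelength_nm": 1314.0,
             "dAD_dCg": -4e-4, "pearson_r": -0.8}
            for i in range(5)
        ]
        summary = cohort_summary(pd.DataFrame(rows))
        by_wl = summary["by_wavelength"]
        assert by_wl["mean_dAD_dCg"].iloc[0] == pytest.approx(-4e-4)
        assert by_wl["sd_dAD_dCg"].iloc[0] == pytest.approx(0.0)

    def test_empty_estimates_rejected(self):
        empty = pd.DataFrame(
            columns=["subject_id", "group", "wavelength_nm", "dAD_dCg", "pearson_r"]
        )
        with pytest.raises(ValueError):
            cohort_summary(empty)

    def test_relative_error_arithmetic(self):
        errors = compare_sensitivities({1314.0: -0.001}, {1314.0: -0.0008})
        assert errors[1314.0] == pytest.approx(20.0)
        assert compare_sensitivities({1550.0: -2.0}, {1550.0: -2.0})[1550.0] == 0.0

    def test_mismatched_wavelengths_rejected(self):
        with pytest.raises(ValueError):
            compare_sensitivities({1314.0: -1.0}, {1550.0: -1.0})

    def test_zero_calculated_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compare_sensitivities({1314.0: 0.0}, {1314.0: -1.0})
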