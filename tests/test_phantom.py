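"""Phantom generator: kinetics, rendering, cohorts, and H/M calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mibgkit import (
    AcquisitionSpec,
    CohortSpec,
    KineticParams,
    calibrate_to_hm_targets,
    default_geometry,
    default_phantom,
    ideal_background_rois,
    measure_scan,
    organ_activity,
    render_frame,
    simulate_cohort,
    simulate_patient_series,
    washout_rate,
)
from mibgkit.exceptions import CalibrationError, ConfigurationError, ValidationError
from mibgkit.phantom import ORGANS, stratified_washouts, triangular_median


class TestOrganActivity:
    def test_pure_neuronal_half_time(self):
        kin = KineticParams(neuronal_fraction=1.0)
        a0 = kin.activities["heart"]
        assert organ_activity(kin, "heart", 112.0) == pytest.approx(a0 / 2)

    def test_pure_extraneuronal_half_time(self):
        kin = KineticParams(neuronal_fraction=0.0)
        a0 = kin.activities["heart"]
        assert organ_activity(kin, "heart", 22.0) == pytest.approx(a0 / 2)

    @pytest.mark.parametrize("organ", ORGANS)
    def test_initial_activity_at_t0(self, organ):
        kin = KineticParams()
        assert organ_activity(kin, organ, 0.0) == pytest.approx(kin.activities[organ])

    def test_unknown_organ_rejected(self):
        with pytest.raises(ConfigurationError):
            organ_activity(KineticParams(), "spleen", 10.0)

    @given(
        t1=st.floats(0, 300),
        dt=st.floats(0.01, 300),
        f=st.floats(0, 1),
        organ=st.sampled_from(ORGANS),
        decay=st.booleans(),
    )
    def test_monotone_non_increasing(self, t1, dt, f, organ, decay):
        kin = KineticParams(neuronal_fraction=f)
        a1 = organ_activity(kin, organ, t1, include_physical_decay=decay)
        a2 = organ_activity(kin, organ, t1 + dt, include_physical_decay=decay)
        assert a2 <= a1 + 1e-12
        assert a2 >= 0


class TestRenderFrame:
    def test_zero_activities_render_empty(self, phantom_pair):
        geometry, kinetics = phantom_pair
        kin = KineticParams(activities={o: 0.0 for o in ORGANS})
        frame = render_frame(geometry, kin, AcquisitionSpec(time_min=60, noise=False))
        assert np.all(frame.counts == 0)

    def test_seeded_noise_reproducible(self, phantom_pair):
        geometry, kinetics = phantom_pair
        acq = AcquisitionSpec(time_min=60, noise=True, seed=42)
        f1 = render_frame(geometry, kinetics, acq)
        f2 = render_frame(geometry, kinetics, acq)
        assert np.array_equal(f1.counts, f2.counts)
        assert f1.counts.min() >= 0

    def test_grid_mismatch_rejected(self, phantom_pair):
        geometry, kinetics = phantom_pair
        with pytest.raises(ConfigurationError):
            render_frame(geometry, kinetics, AcquisitionSpec(time_min=60, matrix=128))

    def test_poisson_mean_matches_noiseless(self):
        # small grid so 500 replicates stay cheap; per-pixel sample mean
        # must sit within 5 sigma / sqrt(N) of the expectation image where
        # the normal approximation holds (>= 10 expected total counts);
        # dimmer PSF-tail pixels get an exact Poisson tail bound instead
        from scipy import stats

        geometry = default_geometry(64)
        kinetics = KineticParams()
        noiseless = render_frame(
            geometry, kinetics, AcquisitionSpec(time_min=60, noise=False)
        ).counts
        n = 500
        acc = np.zeros_like(noiseless)
        for i in range(n):
            acc += render_frame(
                geometry, kinetics, AcquisitionSpec(time_min=60, noise=True, seed=i)
            ).counts
        mean = acc / n
        clt = noiseless * n >= 10
        tol = 5 * np.sqrt(noiseless / n)
        assert np.all(np.abs(mean[clt] - noiseless[clt]) <= tol[clt])
        dim = ~clt & (noiseless > 0)
        upper = stats.poisson.ppf(1 - 1e-9, noiseless[dim] * n)
        assert np.all(acc[dim] <= upper)
        assert np.all(mean[noiseless == 0] == 0)


class TestPatientSeries:
    def test_default_schedule(self, phantom_pair):
        geometry, kinetics = phantom_pair
        acqs = [AcquisitionSpec(time_min=t, noise=False) for t in (15, 60, 120, 180, 240)]
        series = simulate_patient_series(geometry, kinetics, acqs)
        assert len(series.frames) == 5
        assert list(series.truth.time_min) == [15, 60, 120, 180, 240]
        assert list(series.truth.time_label) == ["early", "1h", "2h", "3h", "4h"]

    def test_single_timepoint_has_no_washout_truth(self, phantom_pair):
        geometry, kinetics = phantom_pair
        series = simulate_patient_series(
            geometry, kinetics, [AcquisitionSpec(time_min=60, noise=False)]
        )
        assert len(series.frames) == 1
        assert series.truth.wr_true.isna().all()

    def test_non_increasing_times_rejected(self, phantom_pair):
        geometry, kinetics = phantom_pair
        acqs = [AcquisitionSpec(time_min=t, noise=False) for t in (60, 60)]
        with pytest.raises(ValidationError):
            simulate_patient_series(geometry, kinetics, acqs)

    def test_pure_neuronal_truth_matches_closed_form(self, phantom_pair):
        # with ideal background the true washout is the myocardial
        # clearance itself: 1 - 2**(-dt/112)
        geometry, kinetics = phantom_pair
        kin = KineticParams(activities=kinetics.activities, neuronal_fraction=1.0)
        acqs = [AcquisitionSpec(time_min=t, noise=False) for t in (15, 60, 120, 180, 240)]
        series = simulate_patient_series(geometry, kin, acqs)
        for _, row in series.truth.iloc[1:].iterrows():
            dt = row.time_min - 15.0
            assert row.wr_true / 100 == pytest.approx(1 - 2 ** (-dt / 112.0), abs=1e-9)


class TestCohort:
    def test_default_missingness_one_patient_lacks_4h(self, phantom_pair):
        geometry, kinetics = phantom_pair
        cohort = simulate_cohort(CohortSpec(n=49, noise=False, seed=5), geometry, kinetics)
        assert len(cohort.patients) == 49
        with_4h = sum("4h" in p.labels for p in cohort.patients)
        assert with_4h == 48

    def test_zero_variability_noise_off_patients_identical(self, phantom_pair):
        geometry, kinetics = phantom_pair
        jitter = {k: (v, v, v) for k, v in
                  {"early": 15.0, "1h": 60.0, "2h": 120.0, "3h": 180.0, "4h": 240.0}.items()}
        spec = CohortSpec(
            n=3, heart_cv=0.0, blood_cv=0.0, noise=False, seed=1,
            n_missing_reference=0, jitter_quartiles=jitter,
        )
        cohort = simulate_cohort(spec, geometry, kinetics)
        ref = cohort.patients[0]
        for p in cohort.patients[1:]:
            for fa, fb in zip(ref.frames, p.frames):
                assert np.array_equal(fa.counts, fb.counts)

    def test_master_seed_reproducibility(self, phantom_pair):
        geometry, kinetics = phantom_pair
        spec = CohortSpec(n=3, seed=7)
        c1 = simulate_cohort(spec, geometry, kinetics)
        c2 = simulate_cohort(spec, geometry, kinetics)
        for p1, p2 in zip(c1.patients, c2.patients):
            assert p1.frames[0].time_min == p2.frames[0].time_min
            assert np.array_equal(p1.frames[0].counts, p2.frames[0].counts)

    def test_jitter_median_matches_configured_distribution(self, phantom_pair):
        geometry, kinetics = phantom_pair
        spec = CohortSpec(n=200, noise=False, seed=11, n_missing_reference=0)
        cohort = simulate_cohort(spec, geometry, kinetics)
        one_hour = [
            f.time_min for p in cohort.patients for lab, f in zip(p.labels, p.frames)
            if lab == "1h"
        ]
        expected = triangular_median(*spec.jitter_quartiles["1h"])
        assert np.median(one_hour) == pytest.approx(expected, abs=1.0)


class TestCalibration:
    def test_single_target_reached(self, phantom_pair):
        geometry, kinetics = phantom_pair
        cal = calibrate_to_hm_targets({240.0: 1.52}, geometry, kinetics)
        frame = render_frame(geometry, cal.kinetics, AcquisitionSpec(time_min=240, noise=False))
        assert measure_scan(frame, cal.rois).hm_ratio == pytest.approx(1.52, abs=1e-3)

    def test_unit_ratio_fixed_point(self, phantom_pair):
        geometry, kinetics = phantom_pair
        cal = calibrate_to_hm_targets({120.0: 1.0}, geometry, kinetics)
        frame = render_frame(geometry, cal.kinetics, AcquisitionSpec(time_min=120, noise=False))
        assert measure_scan(frame, cal.rois).hm_ratio == pytest.approx(1.0, abs=1e-3)

    def test_larger_target_needs_more_heart_activity(self, phantom_pair):
        geometry, kinetics = phantom_pair
        activities = {
            tgt: calibrate_to_hm_targets({120.0: tgt}, geometry, kinetics)
            .kinetics.heart_table[0][1]
            for tgt in (1.3, 1.5, 1.7)
        }
        assert activities[1.3] < activities[1.5] < activities[1.7]

    def test_infeasible_target_raises_with_residuals(self, phantom_pair):
        geometry, kinetics = phantom_pair
        with pytest.raises(CalibrationError) as err:
            calibrate_to_hm_targets({120.0: 0.8}, geometry, kinetics)
        assert err.value.residuals  # residuals reported for diagnosis

    def test_calibration_fixed_point_through_pipeline(self, calibrated, phantom_pair):
        geometry, _ = phantom_pair
        for t, target in [(60, 1.60), (120, 1.56), (180, 1.53), (240, 1.52)]:
            frame = render_frame(
                geometry, calibrated.kinetics, AcquisitionSpec(time_min=t, noise=False)
            )
            assert measure_scan(frame, calibrated.rois).hm_ratio == pytest.approx(
                target, abs=1e-3
            )


class TestPhantomInvariants:
    def test_physical_decay_cancels_in_hm(self, phantom_pair):
        geometry, kinetics = phantom_pair
        rois = ideal_background_rois(geometry)
        for t in (15.0, 60.0, 240.0):
            fast = KineticParams(activities=kinetics.activities, t_half_physical=100.0)
            slow = KineticParams(activities=kinetics.activities, t_half_physical=1e9)
            r_fast = measure_scan(
                render_frame(geometry, fast, AcquisitionSpec(time_min=t, noise=False)), rois
            ).hm_ratio
            r_slow = measure_scan(
                render_frame(geometry, slow, AcquisitionSpec(time_min=t, noise=False)), rois
            ).hm_ratio
            assert r_fast == pytest.approx(r_slow, rel=1e-12)

    def test_hm_non_increasing_over_late_window(self, phantom_pair):
        geometry, kinetics = phantom_pair
        kin = KineticParams(activities=kinetics.activities, neuronal_fraction=0.8)
        rois = ideal_background_rois(geometry)
        ratios = [
            measure_scan(
                render_frame(geometry, kin, AcquisitionSpec(time_min=t, noise=False)), rois
            ).hm_ratio
            for t in (60, 120, 180, 240)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(ratios, ratios[1:]))

    def test_noiseless_pipeline_washout_matches_truth(self, phantom_pair):
        # ideal-background phantom: pipeline WR within 0.1 percentage points
        geometry, kinetics = phantom_pair
        rois = ideal_background_rois(geometry)
        acqs = [AcquisitionSpec(time_min=t, noise=False) for t in (15, 60, 120, 180, 240)]
        series = simulate_patient_series(geometry, kinetics, acqs, rois=rois)
        early = measure_scan(series.frames[0], rois)
        for i in range(1, 5):
            late = measure_scan(series.frames[i], rois)
            wr = washout_rate(early, late).wr_percent
            assert wr == pytest.approx(series.truth.wr_true[i], abs=0.1)

    def test_stratified_washouts_hit_mean_exactly(self):
        wr = stratified_washouts(49, mean_wr=34.0, sd_wr=17.0)
        assert wr.mean() == pytest.approx(34.0, abs=1e-12)
        assert np.all((wr > 0) & (wr < 100))
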