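"""Properties of the synthetic signal, day and cohort generators."""
import numpy as np
import pytest

import gaitpal as gp
from gaitpal.errors import ParameterError
from gaitpal.signal_core import recording_counts, vector_magnitude
from gaitpal.synthetic import (CohortSpec, DaySchedule, Segment,
                               gait_params_for_speed, simulate_cohort,
                               simulate_day, simulate_nonwalk,
                               simulate_treadmill_session, simulate_walk)


def test_walk_deterministic_for_fixed_seed():
    a, _ = simulate_walk(gp.GaitParams(), 30.0, seed=42)
    b, _ = simulate_walk(gp.GaitParams(), 30.0, seed=42)
    np.testing.assert_array_equal(a.data, b.data)


def test_noiseless_single_harmonic_matches_counts_oracle():
    # all three axes are pure sinusoids, so counts follow (2/pi) * A * T
    params = gp.GaitParams(step_freq=1.8, amplitude=0.3, harmonics=(),
                           cycle_asymmetry=0.0, noise_sd=0.0)
    rec, _ = simulate_walk(params, 30.0, seed=0)
    counts = recording_counts(rec)
    amp_total = 0.3 * (1.0 + 0.55 + 0.35)  # vertical + attenuated horizontals
    expected = (2 / np.pi) * amp_total * 5.0
    np.testing.assert_allclose(counts, expected, rtol=0.01)


def test_vm_autocorrelation_peaks_at_step_period():
    rec, _ = simulate_walk(gp.GaitParams(noise_sd=0.0), 60.0, seed=3)
    vm = vector_magnitude(rec)
    v = vm - vm.mean()
    acf = np.correlate(v, v, mode="full")[v.size - 1:]
    step_lag = 60.0 / 1.8
    lo, hi = int(0.75 * step_lag), int(1.25 * step_lag)
    peak = lo + int(np.argmax(acf[lo:hi]))
    assert abs(peak - step_lag) <= 1


def test_nonwalk_hits_intensity_target():
    rec, labels = simulate_nonwalk(7.0, 600.0, seed=5)
    counts = recording_counts(rec)
    realized = counts.mean() / 5.0 * 60.0
    assert 6.3 <= realized <= 7.7
    assert set(labels) == {"nonwalk"}


def test_nonwalk_zero_target_is_inactive():
    rec, labels = simulate_nonwalk(0.0, 60.0, seed=5)
    assert set(labels) == {"inactive"}
    assert recording_counts(rec).max() == 0.0


def test_nonwalk_has_no_gait_periodicity(calibrated, rng):
    # sd_cc against the gait template is lower than walking at matched sd_s
    template, _ = calibrated
    from gaitpal.template_features import features_from_vm
    wins, n = 0, 60
    for i in range(n):
        w, _ = simulate_walk(gp.GaitParams(), 5.0, seed=1000 + i)
        nw, _ = simulate_nonwalk(20.0, 5.0, seed=2000 + i)
        vw = vector_magnitude(w)[None, :300]
        vn = vector_magnitude(nw)[None, :300]
        sw, ccw = features_from_vm(vw, template)
        sn, ccn = features_from_vm(vn * (sw[0] / max(vn.std(), 1e-12)), template)
        wins += ccn[0] < ccw[0]
    assert wins >= 0.9 * n


def test_treadmill_session_epoch_count_and_monotonicity():
    rec, labels, speeds = simulate_treadmill_session(seed=7)
    assert labels.size == 144  # 4 x 3 min at 5-s epochs
    assert rec.duration_s == pytest.approx(720.0)
    vm = vector_magnitude(rec).reshape(144, 300)
    sd = vm.std(axis=1)
    block_means = [sd[speeds == s].mean() for s in sorted(set(speeds))]
    assert all(a < b for a, b in zip(block_means, block_means[1:]))


def test_speed_mapping_monotone():
    p3, p6 = gait_params_for_speed(3.0), gait_params_for_speed(6.0)
    assert p6.step_freq > p3.step_freq and p6.amplitude > p3.amplitude


def test_day_short_walk_truth():
    sched = DaySchedule(segments=[Segment("nonwalk", 600.0),
                                  Segment("walk", 55.0),
                                  Segment("nonwalk", 600.0)], seed=1)
    _, labels, truth = simulate_day(sched)
    assert truth.time_min["short_walk"] == pytest.approx(55.0 / 60.0)
    assert truth.time_min["long_walk"] == 0.0


def test_day_nine_hour_wear_invalid():
    sched = DaySchedule(segments=[Segment("nonwalk", 9 * 3600.0)], seed=1)
    _, _, truth = simulate_day(sched)
    assert truth.wear_time_h == pytest.approx(9.0)
    assert not truth.valid


def test_empty_schedule_empty_summary():
    rec, labels, truth = simulate_day(DaySchedule(segments=[], seed=1))
    assert rec.n_samples == 0 and labels.size == 0
    assert truth.activity_counts == 0.0


def test_nonwear_is_exact_zero_and_reduces_wear():
    sched = DaySchedule(segments=[Segment("nonwalk", 2 * 3600.0),
                                  Segment("nonwear", 3 * 3600.0)], seed=1)
    rec, labels, truth = simulate_day(sched)
    assert truth.wear_time_h == pytest.approx(2.0)
    assert np.all(rec.data[-1000:] == 0.0)


def test_schedule_validation():
    with pytest.raises(ParameterError):
        DaySchedule(segments=[Segment("walk", -5.0)])
    with pytest.raises(ParameterError):
        DaySchedule(segments=[Segment("walk", 25 * 3600.0)])


def test_cohort_zero_sd_identical_subjects():
    spec = CohortSpec(n_subjects=3, n_days=5, day_cv=0.0,
                      time_dist={"nonwalking": (500.0, 0.0),
                                 "short_walk": (106.0, 0.0),
                                 "long_walk": (24.0, 0.0)},
                      intensity_dist={"nonwalking": (7.0, 0.0),
                                      "short_walk": (20.9, 0.0),
                                      "long_walk": (23.3, 0.0)},
                      pal_noise_sd=0.0)
    df = simulate_cohort(spec, seed=1)
    assert df["activity_counts"].std() == pytest.approx(0.0, abs=1e-9)
    assert df["nonwalking_counts"].iloc[0] == pytest.approx(3500.0)
    assert df["pal"].iloc[0] == pytest.approx(
        gp.predict_pal_simple(df["activity_counts"].iloc[0]))


def test_cohort_deterministic():
    a = simulate_cohort(CohortSpec(), seed=9)
    b = simulate_cohort(CohortSpec(), seed=9)
    assert a.equals(b)


def test_cohort_truth_satisfies_additive_identities():
    df = simulate_cohort(CohortSpec(), seed=11)
    np.testing.assert_allclose(
        df["walking_counts"],
        df["short_walk_counts"] + df["long_walk_counts"])
    np.testing.assert_allclose(
        df["activity_counts"],
        df["walking_counts"] + df["nonwalking_counts"])
    assert (df["pal"] > 1.0).all()


def test_cohort_pal_range_plausible():
    df = simulate_cohort(CohortSpec(), seed=12)
    # generated PALs should stay near the reference band 1.43-2.36
    assert df["pal"].between(1.1, 2.7).all()
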