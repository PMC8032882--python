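import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grazekit import io_model, synth, trajectory
from grazekit.trajectory import (
    PeakHours,
    active_fraction,
    detect_peak_hours,
    distance_budget,
    diurnal_profile,
    expected_noise_distance,
    log_transform,
    segment_features,
    step_distance,
    tukey_filter,
)

from conftest import make_trajectory

finite_coord = st.floats(-1e6, 1e6, allow_nan=False)


class TestStepDistance:
    @pytest.mark.parametrize(
        "a, b, d",
        [
            ((0.0, 0.0), (3.0, 4.0), 5.0),
            ((600_000.0, 5_710_000.0), (600_000.0, 5_710_000.0), 0.0),
            ((569_000.0, 5_737_000.0), (568_970.0, 5_736_960.0), 50.0),
        ],
    )
    def test_pythagorean_examples(self, a, b, d):
        assert step_distance(a, b) == pytest.approx(d)

    def test_non_finite_coordinate_errors(self):
        with pytest.raises(ValueError):
            step_distance((np.inf, 0.0), (0.0, 0.0))

    @given(
        ax=finite_coord, ay=finite_coord,
        bx=finite_coord, by=finite_coord,
        cx=finite_coord, cy=finite_coord,
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_triangle_inequality(self, ax, ay, bx, by, cx, cy):
        a, b, c = (ax, ay), (bx, by), (cx, cy)
        assert step_distance(a, b) == step_distance(b, a)
        assert step_distance(a, c) <= step_distance(a, b) + step_distance(b, c) + 1e-6


class TestSegmentFeatures:
    def test_heading_clockwise_from_north_and_turns(self):
        # east 10 m, then south 10 m: headings 90, 180; turn +90 (clockwise)
        traj = make_trajectory([(0, 0), (10, 0), (10, -10)])
        seg = segment_features(traj)
        assert seg["heading"].tolist() == pytest.approx([90.0, 180.0])
        assert np.isnan(seg["turn_angle"].iloc[0])
        assert seg["turn_angle"].iloc[1] == pytest.approx(90.0)
        assert seg["speed"].iloc[0] == pytest.approx(10.0 / 60.0)

    def test_collinear_steps_have_zero_turn(self):
        traj = make_trajectory([(0, 0), (5, 5), (10, 10)])
        seg = segment_features(traj)
        assert seg["turn_angle"].iloc[1] == pytest.approx(0.0)

    def test_fewer_than_two_fixes_yield_no_segments(self):
        assert segment_features(make_trajectory([(0, 0)])).empty


class TestDistanceBudget:
    def test_stationary_track_has_zero_budgets(self):
        traj = make_trajectory([(600_000.0, 5_710_000.0)] * 120)
        hourly = distance_budget(traj, "hour")
        assert (hourly["distance"] == 0).all()

    def test_hundred_unit_steps_inside_one_hour(self):
        coords = [(600_000.0 + i, 5_710_000.0) for i in range(101)]
        traj = make_trajectory(coords, start="2017-05-20T08:00:00+00:00", interval=30.0)
        hourly = distance_budget(traj, "hour")
        assert hourly["distance"].iloc[0] == pytest.approx(100.0)

    def test_bucket_sums_match_brute_force_reaccumulation(self, rng):
        coords = 600_000.0 + rng.normal(0, 5, size=(1500, 2)).cumsum(axis=0)
        traj = make_trajectory(coords, interval=128.0)
        hourly = distance_budget(traj, "hour")
        # oracle: assign each raw step to the local hour of its start fix
        local = traj.times.tz_convert(io_model.DEFAULT_TZ)
        oracle = {}
        for i in range(len(traj) - 1):
            key = (local[i].date(), local[i].hour)
            d = np.hypot(
                traj.easting[i + 1] - traj.easting[i],
                traj.northing[i + 1] - traj.northing[i],
            )
            oracle[key] = oracle.get(key, 0.0) + d
        for row in hourly.itertuples():
            assert row.distance == pytest.approx(oracle.get((row.date, row.hour), 0.0))

    def test_hourly_budgets_sum_exactly_to_daily(self, rng):
        coords = 600_000.0 + rng.normal(0, 5, size=(2000, 2)).cumsum(axis=0)
        traj = make_trajectory(coords, start="2017-05-19T22:00:00+00:00", interval=60.0)
        hourly = distance_budget(traj, "hour")
        daily = distance_budget(traj, "day")
        by_day = hourly.groupby("date")["distance"].sum()
        for row in daily.itertuples():
            # same step-assignment rule; equal up to float summation order
            assert by_day[row.date] == pytest.approx(row.distance, rel=1e-12)

    def test_completeness_flags_partial_hours(self):
        coords = [(600_000.0 + i, 5_710_000.0) for i in range(30)]
        traj = make_trajectory(coords, start="2017-05-20T08:00:00+00:00", interval=60.0)
        hourly = distance_budget(traj, "hour")
        assert not hourly["complete"].iloc[0]  # 30 of 60 expected fixes
        assert (hourly["completeness"] <= 1.0).all()


class TestTukeyFilter:
    def test_all_equal_vector_masks_nothing(self):
        kept, mask = tukey_filter([5.0] * 10)
        assert not mask.any() and len(kept) == 10

    def test_hand_computed_fences_mask_only_the_outlier(self):
        # {1..9, 1000}: Q1=3.25, Q3=7.75 (linear interpolation), IQR=4.5,
        # fences [-3.5, 14.5] -> only 1000 is outside
        values = list(range(1, 10)) + [1000.0]
        kept, mask = tukey_filter(values)
        assert mask.tolist() == [False] * 9 + [True]
        assert kept.tolist() == list(map(float, range(1, 10)))

    def test_gaussian_exceedance_near_seven_per_mille(self, rng):
        # Tukey fences on a normal sample exclude ~0.7% of points
        values = rng.normal(0, 1, 10_000)
        _, mask = tukey_filter(values)
        assert 0.004 <= mask.mean() <= 0.011

    def test_idempotent_on_own_output(self, rng):
        values = rng.standard_cauchy(500)
        kept, _ = tukey_filter(values)
        kept2, mask2 = tukey_filter(kept)
        # single-pass semantics: re-filtering may trim more (fences move),
        # but the kept set from the same fences is stable
        q1, q3 = np.percentile(values, [25, 75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        assert ((kept >= lo) & (kept <= hi)).all()

    def test_fewer_than_four_values_warns_and_keeps_all(self):
        with pytest.warns(UserWarning):
            kept, mask = tukey_filter([1.0, 2.0, 3.0])
        assert not mask.any()


class TestLogTransform:
    def test_offset_examples(self):
        assert log_transform([0.0])[0] == pytest.approx(0.0)
        assert log_transform([np.e - 1.0])[0] == pytest.approx(1.0)

    def test_negative_distance_errors(self):
        with pytest.raises(ValueError):
            log_transform([-1.0])

    def test_monotone(self, rng):
        v = np.sort(rng.uniform(0, 5000, 100))
        assert (np.diff(log_transform(v)) >= 0).all()


def _hourly_frame(means_by_hour, n_days=10, noise_sd=0.0, rng=None, collar_id="C1"):
    """Synthetic hourly budget table with planted hourly means."""
    rows = []
    base = dt.date(2017, 5, 19)
    for d in range(n_days):
        for h in range(24):
            m = means_by_hour[h]
            if noise_sd and rng is not None:
                m = max(m + rng.normal(0, noise_sd), 0.0)
            rows.append(
                {
                    "collar_id": collar_id,
                    "date": base + dt.timedelta(days=d),
                    "hour": h,
                    "distance": m,
                    "complete": True,
                }
            )
    return pd.DataFrame(rows)


class TestDiurnalProfileAndPeaks:
    def test_planted_schedule_shows_elevated_hours(self, rng):
        means = [300.0 if h in {5, 6, 7, 19, 20, 21} else 60.0 for h in range(24)]
        hourly = _hourly_frame(means, n_days=30, noise_sd=20.0, rng=rng)
        prof = diurnal_profile(hourly)
        peak_means = prof[prof["hour"].isin({5, 6, 7, 19, 20, 21})]["mean"]
        other_means = prof[~prof["hour"].isin({5, 6, 7, 19, 20, 21})]["mean"]
        assert peak_means.min() > other_means.max()

    def test_single_date_has_undefined_se(self):
        hourly = _hourly_frame([100.0] * 24, n_days=1)
        prof = diurnal_profile(hourly)
        assert prof["se"].isna().all()
        assert (prof["n"] == 1).all()

    def test_bimodal_profile_recovers_planted_peaks(self, rng):
        means = [250.0 if h in {5, 6, 7, 19, 20, 21} else 80.0 for h in range(24)]
        prof = diurnal_profile(_hourly_frame(means, n_days=30, noise_sd=15.0, rng=rng))
        peaks = detect_peak_hours(prof)
        assert peaks.hours == frozenset({5, 6, 7, 19, 20, 21})
        assert peaks.provenance == "detected"

    def test_flat_profile_yields_empty_set_with_warning(self):
        prof = diurnal_profile(_hourly_frame([100.0] * 24, n_days=3))
        with pytest.warns(UserWarning):
            peaks = detect_peak_hours(prof)
        assert peaks.hours == frozenset()

    def test_detected_hours_always_subset_of_day(self, rng):
        for _ in range(20):
            means = rng.uniform(10, 400, 24)
            prof = diurnal_profile(_hourly_frame(list(means), n_days=2))
            try:
                peaks = detect_peak_hours(prof)
            except ValueError:
                continue
            assert set(peaks.hours) <= set(range(24))

    def test_peak_hours_outside_day_rejected(self):
        with pytest.raises(ValueError):
            PeakHours(frozenset({25}), "configured")


class TestActiveFraction:
    def test_all_movement_inside_peaks_is_one(self):
        means = [120.0 if h in {5, 6} else 0.0 for h in range(24)]
        hourly = _hourly_frame(means, n_days=4)
        daily = (
            hourly.groupby(["collar_id", "date"])["distance"].sum().reset_index()
        )
        frac = active_fraction(daily, hourly, PeakHours(frozenset({5, 6}), "configured"))
        assert frac == pytest.approx(1.0)

    def test_uniform_movement_six_peak_hours_is_quarter(self):
        hourly = _hourly_frame([100.0] * 24, n_days=4)
        daily = hourly.groupby(["collar_id", "date"])["distance"].sum().reset_index()
        peaks = PeakHours(frozenset({5, 6, 7, 19, 20, 21}), "configured")
        assert active_fraction(daily, hourly, peaks) == pytest.approx(0.25)

    def test_simulator_ground_truth_fraction_recovered(self, small_bundle):
        # default schedule plants ~40% of daily distance in the peak hours
        collar = next(iter(small_bundle.trajectories))
        traj = io_model.trim_deployment(
            small_bundle.trajectories[collar],
            small_bundle.start_date,
            small_bundle.end_date,
        )
        hourly = distance_budget(traj, "hour")
        daily = distance_budget(traj, "day")
        peaks = PeakHours(
            frozenset(small_bundle.ground_truth[collar].peak_hours), "configured"
        )
        frac = active_fraction(daily, hourly, peaks)
        assert frac == pytest.approx(0.40, abs=0.06)


class TestExpectedNoiseDistance:
    def test_zero_sigma_gives_zero(self):
        assert expected_noise_distance(0.0, 100) == 0.0

    def test_closed_form_28_steps(self):
        assert expected_noise_distance(0.8, 28) == pytest.approx(39.7, abs=0.05)

    def test_monte_carlo_agrees_within_three_se(self, rng):
        sigma, interval, n_hours = 0.8, 128.0, 2000
        traj = synth.simulate_stationary_collar(sigma, interval, n_hours, rng)
        hourly = distance_budget(traj, "hour")
        hourly = hourly[hourly["complete"]]
        mc_mean = hourly["distance"].mean()
        se = hourly["distance"].std(ddof=1) / np.sqrt(len(hourly))
        analytic = expected_noise_distance(sigma, 3600.0 / interval)
        assert abs(mc_mean - analytic) < 3 * se
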