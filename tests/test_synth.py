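import datetime as dt

import numpy as np
import pytest

from grazekit import io_model, synth, trajectory
from grazekit.spatial import assign_time, build_grid, camargo_index
from grazekit.synth import (
    ScheduleEntry,
    SimConfig,
    generate_sward_field,
    sample_plate_meter,
    scenario_suite,
    sigma_from_mean_radial,
    simulate_cow,
    write_bundle,
)


class TestSwardField:
    def test_zero_sd_gives_constant_field(self, rng):
        cfg = SimConfig.for_treatment("L", sd_ho=0.0)
        field = generate_sward_field(cfg, rng)
        assert np.ptp(field.values) == 0.0
        assert field.values[0, 0] == cfg.mean_ho

    def test_realized_moments_near_targets(self):
        # law of large numbers over seeds; the 1-ha lattice has 10^4 points
        # but patches are correlated, so average over several fields
        means, sds = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            cfg = SimConfig.for_treatment("L")
            f = generate_sward_field(cfg, r)
            means.append(f.values.mean())
            sds.append(f.values.std(ddof=1))
        assert np.mean(means) == pytest.approx(cfg.mean_ho, rel=0.03)
        assert np.mean(sds) == pytest.approx(cfg.sd_ho, rel=0.10)

    def test_heterogeneity_ordering_moderate_below_very_lenient(self):
        sds = {}
        for t in ("M", "VL"):
            vals = []
            for seed in range(5):
                r = np.random.default_rng(seed)
                f = generate_sward_field(SimConfig.for_treatment(t), r)
                vals.append(f.values.std(ddof=1))
            sds[t] = np.mean(vals)
        assert sds["M"] < sds["VL"]

    def test_generated_csh_never_negative(self, rng):
        cfg = SimConfig.for_treatment("M")
        field = generate_sward_field(cfg, rng)
        csh, cuts = sample_plate_meter(field, cfg, rng)
        assert (csh["csh_cm"] >= 0).all()
        assert (cuts["csh_cm"] >= 0).all()
        assert (cuts["herbage_g_dm_m2"] >= 0).all()

    def test_gps_sigma_from_mean_radial(self):
        # mean radial deviation of 1.0 m (inside the 0.6-1.9 m collar
        # accuracy band) corresponds to a per-axis SD of ~0.8 m
        assert sigma_from_mean_radial(1.0) == pytest.approx(0.7979, abs=1e-4)


def _quiet_config(**over):
    """Stationary all-day schedule."""
    schedule = (
        ScheduleEntry(tuple(range(24)), "rest", 0.0, 0.0, 0.0, "rest"),
    )
    return SimConfig.for_treatment(
        "L",
        schedule=schedule,
        end_date=dt.date(2017, 5, 20),
        **over,
    )


class TestSimulateCow:
    def test_zero_noise_stationary_cow_never_moves(self, rng):
        cfg = _quiet_config(gps_sigma_axis=0.0)
        traj, _, gt = simulate_cow(cfg, rng)
        assert np.ptp(traj.easting) == 0.0 and np.ptp(traj.northing) == 0.0
        assert (gt.daily["true_distance"] == 0).all()

    def test_noise_free_fixed_steps_recovered_exactly(self, rng):
        # 6 active hours of fixed 1-m steps at 60-s fixes: 60 steps/hour,
        # so each interior day walks exactly 6 * 60 * 1 m = 360 m, and the
        # trajectory module recovers the planted distance exactly
        schedule = (
            ScheduleEntry((5, 6, 7, 19, 20, 21), "graze", 1.0, 1.0, 1.0, "stations"),
            ScheduleEntry(
                tuple(h for h in range(24) if h not in {5, 6, 7, 19, 20, 21}),
                "rest", 0.0, 0.0, 0.0, "rest",
            ),
        )
        cfg = SimConfig(
            treatment="L",
            schedule=schedule,
            fix_interval=60.0,
            step_reference_interval=60.0,
            step_cv=0.0,
            gps_sigma_axis=0.0,
            local_step_factor=1.0,  # no bout slowdown: every step exactly 1 m
            end_date=dt.date(2017, 5, 22),
        )
        traj, _, gt = simulate_cow(cfg, rng)
        trimmed = io_model.trim_deployment(traj, cfg.start_date, cfg.end_date)
        daily = trajectory.distance_budget(trimmed, "day")
        interior = gt.daily[
            (gt.daily["date"] > cfg.start_date) & (gt.daily["date"] < cfg.end_date)
        ]
        assert len(daily) == len(interior) > 0
        for row, true_row in zip(daily.itertuples(), interior.itertuples()):
            assert row.distance == pytest.approx(true_row.true_distance, abs=1e-9)
            assert row.distance == pytest.approx(360.0, rel=0.02)

    def test_default_presets_yield_reported_distance_band(self, small_bundle):
        # daily walking distances of grazing suckler cows fall in the
        # 2,500-4,000 m band
        for collar_id, traj in small_bundle.trajectories.items():
            trimmed = io_model.trim_deployment(
                traj, small_bundle.start_date, small_bundle.end_date
            )
            daily = trajectory.distance_budget(trimmed, "day")
            mean = daily["distance"].mean()
            assert 2500.0 <= mean <= 4000.0, collar_id

    def test_head_tilt_stream_recovers_planted_grazing_minutes(self, small_bundle):
        from grazekit.activity import classify, grazing_minutes

        collar = next(iter(small_bundle.trajectories))
        act = small_bundle.activity[small_bundle.activity["collar_id"] == collar]
        recovered = grazing_minutes(classify(act))
        truth = small_bundle.ground_truth[collar].grazing
        merged = recovered.merge(truth, on=["date", "hour"])
        assert len(merged) == len(truth)
        # planted state is recovered interval-for-interval (the head-up
        # distributions do not straddle the 0.5 threshold)
        assert (merged["n_grazing_x"] == merged["n_grazing_y"]).all()

    def test_schedule_must_cover_every_hour(self):
        with pytest.raises(ValueError, match="cover"):
            SimConfig.for_treatment(
                "L",
                schedule=(ScheduleEntry((1, 2), "x", 0.1, 1.0, 0.1, "rest"),),
            )


class TestScenarioSuite:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        for d in ("a", "b"):
            bundle = scenario_suite(seed=7, n_blocks=1, end_date=dt.date(2017, 5, 22))
            write_bundle(bundle, tmp_path / d)
        for name in ("fixes.csv", "activity.csv", "csh.csv", "calibration.csv",
                     "config.yaml", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_bundle_passes_io_validators(self, small_bundle, tmp_path):
        write_bundle(small_bundle, tmp_path)
        trajs = io_model.read_fixes(tmp_path / "fixes.csv")
        assert set(trajs) == set(small_bundle.trajectories)
        act = io_model.read_activity(tmp_path / "activity.csv")
        assert len(act) == len(small_bundle.activity)
        csh = io_model.read_csh(tmp_path / "csh.csv")
        cuts = io_model.read_calibration(tmp_path / "calibration.csv")
        assert not csh.empty and not cuts.empty
        cfg = io_model.load_config(tmp_path / "config.yaml")
        assert len(cfg.paddocks) == 3 and len(cfg.deployments) == 3

    def test_every_paddock_gets_one_collar(self, small_bundle):
        paddock_ids = {p.paddock_id for p in small_bundle.paddocks}
        collar_paddocks = {d.paddock_id for d in small_bundle.deployments}
        assert paddock_ids == collar_paddocks
        assert len(small_bundle.trajectories) == len(paddock_ids)

    def test_clustered_use_scores_lower_camargo_than_dispersed(self):
        # few feeding stations confined to a small neighbourhood (very
        # lenient-like) concentrate cell time; many stations dispersed over
        # the whole paddock (moderate-like) spread it
        wins = 0
        n_pairs = 15
        for seed in range(n_pairs):
            cams = {}
            for label, stations, spread in (
                ("dispersed", 14, 1.0),
                ("clustered", 4, 0.4),
            ):
                bundle = scenario_suite(
                    seed=1000 + seed,
                    treatments=("L",),
                    n_blocks=1,
                    end_date=dt.date(2017, 5, 22),
                    n_stations=stations,
                    station_spread=spread,
                )
                traj = next(iter(bundle.trajectories.values()))
                paddock = bundle.paddocks[0]
                budget = assign_time(
                    traj, build_grid(paddock.bounds), bundle.fix_interval,
                    allow_outside=True,
                )
                cams[label] = camargo_index(budget)
            wins += cams["clustered"] < cams["dispersed"]
        assert wins >= n_pairs - 1
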