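import numpy as np
import pandas as pd
import pytest

from lge_gv.cgm_io import resample_trace, traces_from_frame
from lge_gv.errors import InvalidConfigError
from lge_gv.experiments import cohort_measures
from lge_gv.gv_metrics import conga, li, mage, mean_sd, modd
from lge_gv.lge import derive_threshold, compute_lge
from lge_gv.meal_events import consolidate_events, match_preprandial, records_from_frame
from lge_gv.synthetic_data import (ParticipantParams, SimConfig, WEEK0_START,
                                   simulate_cohort, simulate_meals, simulate_trace)


def params(baseline=100.0, circ=0.0, amp=60.0, threshold=100.0, days=2, week=0):
    return ParticipantParams(participant_id="P1", week=week, baseline=baseline,
                             circadian_amplitude=circ, meal_amplitude=amp,
                             threshold=threshold, start=WEEK0_START, n_days=days)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"days_per_assessment": 2}, {"days_per_assessment": 11},
        {"cadence_minutes": 7}, {"noise_sd": -1.0},
        {"lge_propensity_range": (0.5, 1.2)}, {"ar_coefficient": 1.0},
        {"snack_noise_fraction": 1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimConfig(**kwargs)

    def test_duration_must_exceed_24h(self):
        with pytest.raises(InvalidConfigError):
            simulate_trace(SimConfig(), params(days=1))


class TestSimulateTrace:
    def test_all_variance_sources_off_gives_constant_trace(self):
        trace = simulate_trace(SimConfig(noise_sd=0.0), params())
        assert np.all(trace.values == 100.0)

    def test_constant_trace_zeroes_every_dispersion_metric(self):
        trace = simulate_trace(SimConfig(noise_sd=0.0), params())
        assert mean_sd(trace)[1] == 0.0
        assert conga(trace) == 0.0
        assert li(trace) == 0.0
        assert mage(trace) == 0.0
        assert modd(trace) == 0.0

    def test_single_meal_peak_height_and_timing(self):
        p = params()
        p.meals = [(12 * 3600.0, 60.0)]
        trace = simulate_trace(SimConfig(noise_sd=0.0), p)
        pre = trace.values[trace.seconds < 12 * 3600][-1]
        post = trace.values[(trace.seconds >= 12 * 3600)
                            & (trace.seconds <= 12 * 3600 + 90 * 60)]
        rise = post.max() - pre
        assert 45.0 <= rise <= 60.0

    def test_same_seed_gives_identical_traces(self):
        cfg = SimConfig(seed=5)
        t1 = simulate_trace(cfg, params(), np.random.default_rng(5))
        t2 = simulate_trace(cfg, params(), np.random.default_rng(5))
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_clip_floor_at_40(self):
        p = params(baseline=42.0, circ=30.0)
        trace = simulate_trace(SimConfig(noise_sd=0.0), p)
        assert trace.values.min() >= 40.0


class TestSimulateMeals:
    def test_propensity_one_zero_noise_gives_100_percent_lge(self):
        cfg = SimConfig(n_participants=4, days_per_assessment=4, noise_sd=0.0,
                        fasting_noise_sd=0.0, propensity_shift_max=0.0,
                        lge_propensity_range=(1.0, 1.0),
                        snack_noise_fraction=0.0, seed=11)
        cohort = simulate_cohort(cfg)
        measures = cohort_measures(cohort)
        assert (measures["lge_percent"] == 100.0).all()

    def test_propensity_zero_high_baseline_gives_lge_near_zero(self):
        # threshold far below the trace: no random meal can be low-glucose
        cfg = SimConfig(noise_sd=0.0, snack_noise_fraction=0.0, seed=2)
        p = params(baseline=110.0, circ=10.0, threshold=70.0, days=4)
        rng = np.random.default_rng(7)
        food = simulate_meals(cfg, p, lge_propensity=0.0, rng=rng)
        trace = simulate_trace(cfg, p)
        events = match_preprandial(consolidate_events(records_from_frame(food)),
                                   resample_trace(trace))
        thr = derive_threshold("P1", 0, (70.0, 70.0))
        res = compute_lge(events, thr)
        # brute-force recount: matched preprandial values vs the threshold
        recount = [ev.preprandial_glucose <= 70.0 for ev in events if ev.matched]
        assert res.lge_percent == pytest.approx(100.0 * np.mean(recount))
        assert res.lge_percent <= 5.0

    def test_invalid_propensity_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_meals(SimConfig(), params(), 1.5, np.random.default_rng(0))

    def test_snack_noise_half_drops_about_half_of_records(self):
        cfg = SimConfig(snack_noise_fraction=0.5, seed=3)
        cohort = simulate_cohort(cfg)
        kcal = cohort.food_logs["kcal"]
        frac_small = (kcal < 25).mean()
        assert 0.35 <= frac_small <= 0.65

    def test_meals_are_at_least_15_min_apart_so_none_merge(self):
        cohort = simulate_cohort(SimConfig(n_participants=3, seed=4))
        for (_, _), grp in cohort.food_logs.groupby(["participant_id", "week"]):
            t = grp["timestamp"].sort_values()
            gaps = t.diff().dropna().dt.total_seconds() / 60
            assert (gaps >= 15).all()


class TestSimulateCohort:
    def test_participant_counts_in_all_tables(self):
        cfg = SimConfig(n_participants=17, days_per_assessment=7, seed=0)
        cohort = simulate_cohort(cfg)
        for df in (cohort.cgm, cohort.food_logs, cohort.anthropometrics,
                   cohort.truth):
            assert df["participant_id"].nunique() == 17

    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimConfig(n_participants=3, days_per_assessment=3, seed=9)
        p1 = simulate_cohort(cfg).write_csvs(tmp_path / "a")
        p2 = simulate_cohort(cfg).write_csvs(tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_meal_timestamps_inside_wear_periods(self):
        cohort = simulate_cohort(SimConfig(n_participants=4, seed=6))
        traces = traces_from_frame(cohort.cgm).by_assessment()
        for (pid, week), grp in cohort.food_logs.groupby(["participant_id", "week"]):
            tr = traces[(str(pid), week)]
            assert (grp["timestamp"] >= tr.timestamps[0]).all()
            assert (grp["timestamp"] <= tr.timestamps[-1]).all()

    def test_glucose_never_below_40(self):
        cohort = simulate_cohort(SimConfig(n_participants=5, noise_sd=15.0, seed=8))
        assert (cohort.cgm["glucose_mg_dl"] >= 40.0).all()

    def test_negative_effect_plants_negative_truth_correlation(self):
        cfg = SimConfig(n_participants=40, days_per_assessment=3, effect_size=-40.0, seed=12)
        t = simulate_cohort(cfg).truth
        dprop = t["propensity_week16"] - t["propensity_week0"]
        dgv = t["gv_level_week16"] - t["gv_level_week0"]
        assert np.corrcoef(dprop, dgv)[0, 1] < 0

    def test_zero_effect_gives_null_truth_correlation_in_expectation(self):
        rs = []
        for seed in range(15):
            cfg = SimConfig(n_participants=40, days_per_assessment=3,
                            effect_size=0.0, seed=seed)
            t = simulate_cohort(cfg).truth
            dprop = t["propensity_week16"] - t["propensity_week0"]
            dgv = t["gv_level_week16"] - t["gv_level_week0"]
            rs.append(np.corrcoef(dprop, dgv)[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_lge_percent_rank_correlates_with_true_propensity(self):
        from scipy.stats import spearmanr
        cfg = SimConfig(n_participants=40, seed=13)
        cohort = simulate_cohort(cfg)
        measures = cohort_measures(cohort)
        truth = cohort.truth.set_index("participant_id")
        wk0 = measures[measures["week"] == 0].set_index("participant_id")
        rho, _ = spearmanr(truth.loc[wk0.index, "propensity_week0"],
                           wk0["lge_percent"])
        assert rho >= 0.7
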