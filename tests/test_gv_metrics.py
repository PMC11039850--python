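import numpy as np
import pandas as pd
import pytest

from lge_gv.errors import InsufficientDataError
from lge_gv.gv_metrics import (MGDL_PER_MMOL, RISK_ROOT_MGDL, adrr, bgi, conga,
                               grade, gv_profile, j_index, li, m_value, mage,
                               mean_sd, modd)

import oracles
from conftest import START, make_trace, random_walk_trace


class TestMeanSd:
    def test_constant_trace(self, constant_trace):
        assert mean_sd(constant_trace) == (100.0, 0.0)

    def test_hand_arithmetic_sample_divisor(self):
        m, s = mean_sd(make_trace([90, 100, 110]))
        assert (m, s) == (100.0, pytest.approx(10.0))

    def test_single_reading_insufficient_for_sd(self):
        with pytest.raises(InsufficientDataError):
            mean_sd(make_trace([100]))


class TestConga:
    def test_constant_trace_is_zero(self, constant_trace):
        assert conga(constant_trace) == 0.0

    def test_hand_arithmetic_at_30min_spacing(self):
        trace = make_trace([100, 120, 90, 110, 100], cadence_minutes=30)
        # differences at lag 60 min: -10, -10, +10; sample SD 11.547 mg/dL
        assert conga(trace, 60) == pytest.approx(11.547005 / MGDL_PER_MMOL, rel=1e-6)

    def test_trace_shorter_than_lag_raises(self):
        with pytest.raises(InsufficientDataError):
            conga(make_trace([100, 105, 102]), 60)  # spans 30 min


class TestLi:
    def test_constant_trace_is_zero(self, constant_trace):
        assert li(constant_trace) == 0.0

    def test_hourly_5_6_5_mmol_gives_2(self):
        vals = np.array([5.0, 6.0, 5.0]) * MGDL_PER_MMOL
        trace = make_trace(vals, cadence_minutes=60)
        assert li(trace, 60) == pytest.approx(2.0, rel=1e-9)

    def test_doubling_deviations_quadruples_li(self, rng):
        vals = rng.uniform(80, 160, size=48)
        trace = make_trace(vals, cadence_minutes=60)
        doubled = make_trace(vals.mean() + 2 * (vals - vals.mean()),
                             cadence_minutes=60)
        assert li(doubled, 60) == pytest.approx(4 * li(trace, 60), rel=1e-9)


class TestJIndex:
    def test_mean_100_sd_10_gives_12_1(self):
        assert j_index(make_trace([90, 100, 110])) == pytest.approx(12.1)

    def test_constant_100_gives_10(self, constant_trace):
        assert j_index(constant_trace) == pytest.approx(10.0)

    def test_strictly_increasing_in_mean_and_sd(self):
        base = j_index(make_trace([90, 100, 110]))
        assert j_index(make_trace([95, 105, 115])) > base       # mean up
        assert j_index(make_trace([85, 100, 115])) > base       # sd up


class TestBgi:
    def test_risk_root_gives_zero_both_sides(self):
        lbgi, hbgi = bgi(make_trace([112.5] * 10))
        assert abs(lbgi) <= 1e-3 and abs(hbgi) <= 1e-3
        assert RISK_ROOT_MGDL == pytest.approx(112.5, abs=0.05)

    def test_constant_180_high_side_only(self):
        lbgi, hbgi = bgi(make_trace([180.0] * 10))
        assert lbgi == 0.0
        assert hbgi == pytest.approx(7.733, abs=0.01)

    def test_constant_50_low_side_only(self):
        lbgi, hbgi = bgi(make_trace([50.0] * 10))
        assert hbgi == 0.0
        assert lbgi == pytest.approx(22.5, abs=0.01)

    def test_monotone_in_constant_level(self):
        levels = [60, 80, 100, 120, 150, 200]
        lbgis = [bgi(make_trace([g] * 5))[0] for g in levels]
        hbgis = [bgi(make_trace([g] * 5))[1] for g in levels]
        assert all(a >= b for a, b in zip(lbgis, lbgis[1:]))
        assert all(a <= b for a, b in zip(hbgis, hbgis[1:]))


class TestAdrr:
    def test_zero_risk_day(self):
        assert adrr(make_trace([112.494] * 96)) == pytest.approx(0.0, abs=1e-3)

    def test_two_constant_days(self):
        trace = make_trace([50.0] * 96 + [180.0] * 96)
        assert adrr(trace) == pytest.approx((22.505 + 7.733) / 2, abs=0.02)

    def test_duplicate_daily_max_leaves_adrr_unchanged(self):
        vals = [100.0] * 95 + [180.0]
        base = adrr(make_trace(vals))
        vals2 = [100.0] * 94 + [180.0, 180.0]
        assert adrr(make_trace(vals2)) == pytest.approx(base, rel=1e-12)

    def test_sparse_days_excluded(self):
        # 96-reading day then an 8-reading day: only day 1 qualifies
        trace = make_trace([50.0] * 96 + [180.0] * 8)
        assert adrr(trace) == pytest.approx(22.505, abs=0.01)


class TestGrade:
    def test_constant_5_5_mmol(self):
        trace = make_trace([5.5 * MGDL_PER_MMOL] * 10)
        assert grade(trace) == pytest.approx(0.368, abs=1e-3)

    def test_analytic_minimum_near_4_918_mmol(self):
        trace = make_trace([4.918 * MGDL_PER_MMOL] * 10)
        assert grade(trace) <= 1e-3

    def test_cap_at_50(self):
        trace = make_trace([2.0 * MGDL_PER_MMOL] * 10)
        assert grade(trace) == 50.0


class TestMage:
    def test_constant_trace_is_zero_flagged(self, constant_trace):
        assert mage(constant_trace) == 0.0
        assert gv_profile(make_trace([100.0] * 200)).mage_no_excursions

    def test_hand_traced_turning_points(self):
        vals = [90, 120, 150, 120] * 3  # SD ~24.5; excursions of 60 mg/dL
        assert mage(make_trace(vals)) == pytest.approx(60 / MGDL_PER_MMOL, rel=1e-9)

    def test_strictly_monotone_trace_is_zero(self):
        assert mage(make_trace(np.linspace(90, 180, 20))) == 0.0

    def test_fewer_than_4_readings_raises(self):
        with pytest.raises(InsufficientDataError):
            mage(make_trace([90, 100, 95]))


class TestModd:
    def test_identical_days_give_zero(self):
        day = list(np.linspace(90, 150, 96))
        assert modd(make_trace(day + day)) == 0.0

    def test_constant_daily_offset_of_one_mmol(self):
        day = np.linspace(90, 150, 96)
        trace = make_trace(np.concatenate([day, day + MGDL_PER_MMOL]))
        assert modd(trace) == pytest.approx(1.0, rel=1e-9)

    def test_20_hour_trace_raises(self):
        with pytest.raises(InsufficientDataError):
            modd(make_trace([100] * 80))  # spans < 20 h


class TestMValue:
    def test_reference_identity(self):
        assert m_value(make_trace([120.0] * 10)) == 0.0

    def test_constant_240(self):
        assert m_value(make_trace([240.0] * 10)) == pytest.approx(27.28, abs=0.01)

    def test_log_symmetry_of_60_and_240(self):
        assert (m_value(make_trace([60.0] * 10))
                == pytest.approx(m_value(make_trace([240.0] * 10)), rel=1e-12))


class TestTimeShiftInvariance:
    def test_metrics_invariant_to_uniform_shift(self, rng):
        trace = random_walk_trace(rng, n_days=2)
        shifted = make_trace(trace.values,
                             timestamps=trace.timestamps + pd.Timedelta(days=3),
                             cadence_minutes=15)
        for fn in (lambda t: mean_sd(t)[1], conga, li, j_index,
                   lambda t: bgi(t)[0], grade, mage, modd, m_value, adrr):
            assert fn(shifted) == pytest.approx(fn(trace), rel=1e-12)


class TestOracleAgreement:
    """Spot-check vectorized metrics against naive-loop oracles (full 200-trace
    sweep lives in the acceptance tests)."""

    def test_random_traces_match_naive_oracles(self, rng):
        for _ in range(20):
            trace = random_walk_trace(rng, n_days=2)
            sec = trace.seconds
            vals = list(trace.values)
            dates = [ts.date() for ts in trace.timestamps]
            m, s = mean_sd(trace)
            om, os = oracles.naive_mean_sd(vals)
            assert m == pytest.approx(om, rel=1e-9)
            assert s == pytest.approx(os, rel=1e-9)
            assert conga(trace) == pytest.approx(
                oracles.naive_conga(sec, vals), rel=1e-9)
            assert li(trace) == pytest.approx(
                oracles.naive_li(sec, vals), rel=1e-9)
            assert j_index(trace) == pytest.approx(
                oracles.naive_j_index(vals), rel=1e-9)
            lb, hb = bgi(trace)
            olb, ohb = oracles.naive_bgi(vals)
            assert lb == pytest.approx(olb, rel=1e-9, abs=1e-12)
            assert hb == pytest.approx(ohb, rel=1e-9, abs=1e-12)
            assert adrr(trace) == pytest.approx(
                oracles.naive_adrr(dates, vals), rel=1e-9)
            assert grade(trace) == pytest.approx(
                oracles.naive_grade(vals), rel=1e-9)
            assert mage(trace) == pytest.approx(
                oracles.naive_mage(vals), rel=1e-9, abs=1e-12)
            assert modd(trace) == pytest.approx(
                oracles.naive_modd(sec, vals), rel=1e-9)
            assert m_value(trace) == pytest.approx(
                oracles.naive_m_value(vals), rel=1e-9)
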