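"""Response timing, calibration, lag, lineage, decay and fate analyses."""

import math

import numpy as np
import pandas as pd
import pytest

import trenchox as tx
from trenchox import response as rs


def grid(start=-30.0, stop=120.0, dt=3.0):
    return np.arange(start, stop + dt / 2, dt)


class TestDetectPeak:
    def test_flat_trace_reports_missing_peak(self):
        t = grid()
        pt, amp = rs.detect_peak(np.full(t.size, 5.0), t)
        assert math.isnan(pt) and math.isnan(amp)

    def test_triangular_bump_apex(self):
        t = grid()
        y = np.full(t.size, 100.0)
        k = np.searchsorted(t, 30.0)
        y[k - 2: k + 3] = [300, 600, 900, 600, 300]
        pt, amp = rs.detect_peak(y, t)
        assert pt == pytest.approx(t[k])
        assert amp == pytest.approx(900.0 - 100.0)

    def test_adjacent_candidates_keep_first(self):
        t = grid()
        y = np.full(t.size, 0.0)
        k = np.searchsorted(t, 30.0)
        y[k] = 800.0
        y[k + 1] = 800.0  # plateau: two candidates one frame apart
        pt, _ = rs.detect_peak(y, t)
        assert pt == pytest.approx(t[k])

    def test_subthreshold_bump_is_missing(self):
        t = grid()
        y = np.linspace(0.0, 1000.0, t.size)  # monotone: no local maximum
        y[5] += 1.0
        pt, _ = rs.detect_peak(y, t)
        assert math.isnan(pt)


class TestInductionTime:
    def test_step_crossing_interpolated(self):
        t = grid(0.0, 30.0)
        y = np.where(t >= 12.0, 2000.0, 0.0)
        # linear interpolation between the t=9 and t=12 samples
        expect = 9.0 + 3.0 * 1480.0 / 2000.0
        assert rs.induction_time(y, t) == pytest.approx(expect)

    def test_ramp_crossing_matches_closed_form(self):
        t = grid(0.0, 60.0)
        y = 100.0 * t  # crosses 1480 at t = 14.8
        assert rs.induction_time(y, t) == pytest.approx(14.8)

    def test_never_crossing_gives_nan(self):
        t = grid(0.0, 60.0)
        assert math.isnan(rs.induction_time(np.full(t.size, 10.0), t))


class TestCV:
    def test_identical_values_zero(self):
        assert rs.cv([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed_pair(self):
        # {1, 3}: population SD 1, mean 2
        assert rs.cv([1.0, 3.0]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        vals = [2.0, 3.0, 7.0, 4.0]
        assert rs.cv(vals) == pytest.approx(rs.cv([10 * v for v in vals]))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            rs.cv([-1.0, 1.0])


class TestCalibration:
    def test_exact_linear_panel_recovered(self):
        panel = {c: 50.0 + 12.0 * c for c in rs.CALIBRATION_PANEL_UM}
        cal = rs.calibrate(panel)
        assert cal.slope_au_per_uM == pytest.approx(12.0)
        assert cal.intercept_au == pytest.approx(50.0)
        assert cal.r_squared == pytest.approx(1.0)
        assert cal.to_concentration(50.0 + 12.0 * 37.5) == pytest.approx(37.5)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            rs.calibrate({50.0: 600.0, 100.0: 1200.0})

    def test_panel_is_the_documented_seven(self):
        assert rs.CALIBRATION_PANEL_UM == (12.5, 25.0, 37.5, 50.0, 62.5, 75.0, 100.0)


class TestInferAttenuation:
    def test_exact_geometric_data(self):
        B = np.repeat(np.arange(8), 5)
        c = 100.0 * 0.7 ** B
        f, ci = rs.infer_attenuation(c, B, n_boot=50, seed=1)
        assert f == pytest.approx(0.3, abs=1e-9)
        assert ci[0] <= 0.3 <= ci[1] + 1e-9

    def test_constant_concentrations_give_zero(self):
        B = np.arange(6)
        f, _ = rs.infer_attenuation(np.full(6, 40.0), B, n_boot=10)
        assert f == 0.0

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            rs.infer_attenuation([10.0, -1.0, 5.0], [0, 1, 2])


class TestCrossCorrelation:
    def test_planted_shift_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        k = 5
        y = -np.roll(x, k)[k:]  # y_t = -x_{t-k}
        x = x[k:]
        lag, corr = rs.cross_correlation_lag(y, x, dt_min=3.0, max_lag=15)
        assert lag == pytest.approx(k * 3.0)
        assert corr == pytest.approx(-1.0, abs=1e-9)

    def test_white_noise_extremum_within_permutation_band(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        _, corr = rs.cross_correlation_lag(y, x, dt_min=1.0, max_lag=20)
        # 95% permutation band for the most negative value over 41 lags
        extremes = []
        for _ in range(200):
            perm = rng.permutation(y)
            _, c = rs.cross_correlation_lag(perm, x, dt_min=1.0, max_lag=20)
            extremes.append(c)
        band = np.percentile(extremes, 2.5)
        assert corr >= band  # no more extreme than the null

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            rs.cross_correlation_lag(np.ones(10), np.ones(10), 1.0)


class TestFate:
    def test_flat_length_for_eleven_hours_is_dead(self):
        t = np.arange(0.0, 700.0, 3.0)
        fate, _ = rs.classify_fate(np.full(t.size, 2.0), t, removal_time=0.0)
        assert fate == "dead"

    def test_immediate_regrowth_recovered_at_zero(self):
        t = np.arange(0.0, 700.0, 3.0)
        L = 2.0 * np.exp(0.02 * t)
        L = np.where(L > 4.0, 2.0 * np.exp(0.02 * (t % 35)), L)  # crude divisions
        fate, rt = rs.classify_fate(L, t, removal_time=0.0)
        assert fate == "recovered"
        assert rt <= 6.0

    def test_delayed_regrowth_time_located(self):
        t = np.arange(0.0, 700.0, 3.0)
        L = np.where(t < 240.0, 2.0, 2.0 * np.exp(0.025 * np.maximum(t - 240.0, 0)))
        L = np.minimum(L, 4.0)  # cap instead of dividing; still fast growth
        fate, rt = rs.classify_fate(L, t, removal_time=0.0)
        assert fate == "recovered"
        assert abs(rt - 240.0) <= 6.0

    def test_short_observation_undetermined(self):
        t = np.arange(0.0, 120.0, 3.0)
        fate, _ = rs.classify_fate(np.full(t.size, 2.0), t, removal_time=0.0)
        assert fate == "undetermined"


class TestMismatchRate:
    def table(self, foci_per_frame, n_cells=10, dt=3.0):
        rows = []
        for k, f in enumerate(foci_per_frame):
            for i in range(n_cells):
                rows.append(dict(trench_id=0, frame=k, time_min=k * dt,
                                 cell_index=i, foci_count=f if i == 0 else 0))
        return pd.DataFrame(rows)

    def test_zero_foci_zero_rate(self):
        out = rs.mismatch_rate(self.table([0, 0, 0]))
        assert (out.rate == 0).all()

    def test_one_focus_per_ten_cells_arithmetic(self):
        # 1 focus / 10 cells / 3 min frame = 1/30 per cell per minute
        out = rs.mismatch_rate(self.table([1, 1, 1]))
        assert np.allclose(out.rate, 1.0 / 30.0)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            rs.mismatch_rate(pd.DataFrame({"frame": [0], "time_min": [0.0]}))


class TestDecayAnalysis:
    def synthetic_dilution_table(self, betas, seed=0):
        """Mothers with pure exponential dilution of the reporter after
        removal at t = 0; intensity I = basal + I0 exp(-beta t)."""
        rng = np.random.default_rng(seed)
        rows = []
        t = np.arange(-30.0, 90.0, 3.0)
        for j, beta in enumerate(betas):
            area = 2.4 * np.exp(beta * np.maximum(t, 0.0))
            area = 2.4 * (area / area)  # keep area bookkeeping simple below
            I = 400.0 + 5000.0 * np.exp(-beta * np.maximum(t, 0.0))
            for k, (tt, ii) in enumerate(zip(t, I)):
                rows.append(dict(trench_id=j, frame=k, time_min=tt, cell_index=0,
                                 cell_id=j, reporter_au=ii,
                                 area_um2=2.4 * math.exp(beta * max(tt, 0.0))))
        return pd.DataFrame(rows)

    def test_pure_dilution_half_life_matches_doubling_time(self):
        betas = [0.022, 0.025, 0.028, 0.031, 0.034]
        df = self.synthetic_dilution_table(betas)
        res = rs.decay_analysis(df, removal_time=0.0, window_min=60.0,
                                baseline=400.0)
        assert res["half_life_min"] == pytest.approx(res["doubling_time_min"],
                                                     rel=0.05)

    def test_faster_growers_decay_faster(self):
        betas = np.linspace(0.015, 0.04, 12)
        df = self.synthetic_dilution_table(betas)
        res = rs.decay_analysis(df, removal_time=0.0, baseline=400.0)
        assert res["correlation"] > 0.95

    def test_non_growing_cell_dropped_not_crashing(self):
        df = self.synthetic_dilution_table([0.0, 0.025, 0.028, 0.031])
        res = rs.decay_analysis(df, removal_time=0.0, baseline=400.0)
        assert len(res["per_cell"]) >= 3


class TestLineageHelpers:
    def test_duplicated_traces_fully_correlated(self):
        # two sisters carrying identical intensities -> r = 1
        rows = []
        for k in range(60):
            for i, cid in enumerate((10, 11)):
                rows.append(dict(trench_id=0, frame=k, time_min=120.0 + 3.0 * k,
                                 cell_index=i, cell_id=cid, parent_id=1,
                                 reporter_au=100.0 + 7.0 * k))
        df = pd.DataFrame(rows)
        out = rs.lineage_correlations(df, steady_from_min=0.0, min_pairs=5,
                                      frame_stride=1)
        assert list(out.relation) == ["sister"]
        assert out.r.iloc[0] == pytest.approx(1.0)

    def test_identical_sisters_do_not_diverge(self):
        rows = []
        # parent present at frame 0, sisters from frame 1 with equal traces
        rows.append(dict(trench_id=0, frame=0, time_min=150.0, cell_index=0,
                         cell_id=1, parent_id=-1, reporter_au=1000.0))
        for k in range(1, 15):
            for i, cid in enumerate((2, 3)):
                rows.append(dict(trench_id=0, frame=k, time_min=150.0 + 3.0 * k,
                                 cell_index=i, cell_id=cid, parent_id=1,
                                 reporter_au=900.0 - 5.0 * k))
        df = pd.DataFrame(rows)
        out = rs.sister_divergence(df, steady_from_min=0.0)
        assert (out.divergence == 0).all()
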