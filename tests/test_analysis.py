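import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import microstat as ms
from microstat.errors import DomainError, FitError, StateError
from microstat.logio import ExperimentLog


def make_log(sample_Ts, sample_times=None, events=None, polarity="growth_decreases_T"):
    """Hand-built log: transmittance samples plus refresh events."""
    records = []
    times = sample_times or list(range(len(sample_Ts)))
    for t, T in zip(times, sample_Ts):
        records.append(
            {"time_s": float(t), "channel": 1, "raw": T / 10.0, "transmittance_pct": T,
             "filtered_pct": T, "phase": "idle", "event": "", "pinch_time_s": np.nan,
             "volume_added_mL": np.nan, "volume_removed_mL": np.nan,
             "cumulative_medium_mL": np.nan}
        )
    for t, v in events or []:
        records.append(
            {"time_s": float(t), "channel": 1, "raw": np.nan, "transmittance_pct": np.nan,
             "filtered_pct": np.nan, "phase": "refreshing", "event": "refresh_cycle",
             "pinch_time_s": v, "volume_added_mL": v, "volume_removed_mL": v,
             "cumulative_medium_mL": np.nan}
        )
    records.sort(key=lambda r: r["time_s"])
    metadata = {"config": {"vessel": {"working_volume": 20.0}, "polarity": polarity}}
    return ExperimentLog.from_records(records, metadata)


class TestLinearFit:
    def test_exact_line(self):
        xs = np.arange(5.0)
        fit = ms.linear_fit(xs, 2 * xs + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        fit = ms.linear_fit([0, 1, 2], [5.0, 5.0, 5.0])
        assert fit.slope == 0.0 and fit.r2 == 0.0

    def test_normal_equations_example(self):
        fit = ms.linear_fit([0, 1, 2], [0, 1, 1])
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(1 / 6)

    def test_degenerate_x_rejected(self):
        with pytest.raises(FitError):
            ms.linear_fit([1.0, 1.0, 1.0], [0, 1, 2])
        with pytest.raises(FitError):
            ms.linear_fit([1.0], [2.0])

    @given(
        st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=3, max_size=10
        )
    )
    def test_matches_normal_equations_oracle(self, pts):
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        if np.ptp(xs) < 1e-6 or np.ptp(ys) < 1e-9:
            return
        X = np.column_stack([xs, np.ones_like(xs)])
        beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
        fit = ms.linear_fit(xs, ys)
        assert fit.slope == pytest.approx(beta[0], rel=1e-6, abs=1e-9)
        assert fit.intercept == pytest.approx(beta[1], rel=1e-6, abs=1e-9)


class TestCalibrationFits:
    OPT = ms.OpticalModelParams(k_cell=2e-9, path_length=1.0)

    def _beer_lambert_points(self):
        X = np.logspace(7, 9, 40)
        T = np.array(
            [ms.transmittance_from_components(ms.cell_absorbance(x, self.OPT), 0.0) for x in X]
        )
        return np.column_stack([T, X])

    def test_window_excludes_and_fits_well(self):
        pts = self._beer_lambert_points()
        fit = ms.fit_transmittance_vs_logcfu(pts, (25.0, 70.0))
        assert fit.n_excluded == len(pts) - fit.n_used > 0
        assert fit.r2 > 0.98
        assert fit.slope < 0  # denser culture -> lower transmittance

    def test_all_points_in_range(self):
        pts = self._beer_lambert_points()
        fit = ms.fit_transmittance_vs_logcfu(pts, (-1.0, 101.0))
        assert fit.n_excluded == 0

    def test_empty_window_rejected(self):
        with pytest.raises(FitError):
            ms.fit_transmittance_vs_logcfu(self._beer_lambert_points(), (0.0, 0.0))

    def test_ph_fit_matches_linearized_slope(self):
        params = ms.OpticalModelParams(
            phenolred_A_min=-math.log10(0.16), phenolred_A_max=-math.log10(0.08)
        )
        pH = np.linspace(6.0, 7.0, 21)
        T = np.array(
            [ms.transmittance_from_components(0.0, ms.phenolred_absorbance(p, params)) for p in pH]
        )
        fit = ms.fit_transmittance_vs_pH(np.column_stack([T, pH]), (6.0, 7.0))
        assert fit.r2 > 0.99  # near-linear over the indicator window
        # linearization about the window: dT/dpH = -ln10 (A_max-A_min) T
        expected = -math.log(10) * (params.phenolred_A_max - params.phenolred_A_min) * T.mean()
        assert fit.slope == pytest.approx(expected, rel=0.05)

    def test_ph_window_exclusion(self):
        pts = np.array([[10.0, 5.0], [12.0, 6.2], [11.0, 6.8], [9.0, 7.5]])
        fit = ms.fit_transmittance_vs_pH(pts, (6.0, 7.0))
        assert fit.n_used == 2 and fit.n_excluded == 2

    def test_flow_calibration_recovery(self):
        calib = ms.FlowCalibration(rate=1.3, dead_time=0.4)
        t = np.linspace(1.0, 30.0, 15)
        v = np.array([ms.volume_delivered(ti, calib) for ti in t])
        fit = ms.fit_flow_calibration(np.column_stack([t, v]))
        assert fit.slope == pytest.approx(1.3, rel=1e-9)
        assert -fit.intercept / fit.slope == pytest.approx(0.4, rel=1e-9)


class TestGrowthRate:
    def test_recovers_exponential_rate(self):
        mu = 0.9
        t = np.arange(0, 7200, 60.0)
        A0 = 0.05
        T = 100 * 10 ** (-(A0 * np.exp(mu * t / 3600.0)))
        log = make_log(T.tolist(), sample_times=t.tolist())
        assert ms.estimate_growth_rate(log, (0.0, 7200.0)) == pytest.approx(mu, rel=1e-6)

    def test_constant_transmittance_gives_zero(self):
        log = make_log([50.0] * 10)
        assert ms.estimate_growth_rate(log, (0.0, 9.0)) == 0.0

    def test_interval_spanning_refresh_rejected(self):
        log = make_log([60.0] * 10, events=[(4.5, 3.0)])
        with pytest.raises(StateError):
            ms.estimate_growth_rate(log, (0.0, 9.0))


class TestGenerations:
    def test_steady_state_dilution_doublings(self):
        events = [(i * 100.0 + 0.5, 20.0) for i in range(25)]  # 25 half-dilutions
        log = make_log([50.0, 50.0], sample_times=[0.0, 2600.0], events=events)
        est = ms.generations_from_log(log)
        assert est.generations == pytest.approx(25.0)
        assert not est.corrected

    def test_end_state_correction_without_refreshes(self):
        # turbidity doubles (absorbance ratio 2) with no dilution: 1 generation
        T0 = 100 * 10**-0.1
        T1 = 100 * 10**-0.2
        log = make_log([T0, T1], sample_times=[0.0, 1000.0])
        est = ms.generations_from_log(log)
        assert est.corrected
        assert est.generations == pytest.approx(1.0)

    def test_simulated_turbidostat_generation_count(self, ecoli_grid_log):
        """~25 generations over 12 h for a doubling time of 0.48 h."""
        est = ms.generations_from_log(ecoli_grid_log)
        assert est.generations == pytest.approx(25.0, abs=1.0)

    def test_agrees_with_simulator_growth_integral(self):
        cfg = ms.preset("ecoli-like", duration_h=12.0)
        rig = ms.build_rig(cfg.channels[0], cfg.seed)
        log = ms.run_experiment(rig, ms.to_experiment_config(cfg.channels[0]))
        est = ms.generations_from_log(log)
        assert est.generations == pytest.approx(rig.growth_integral / math.log(2), rel=0.02)


class TestSteadyStateSummary:
    def test_constant_series(self):
        s = ms.steady_state_summary([7.0] * 6)
        assert s.median == s.Q1 == s.Q3 == s.whisker_low == s.whisker_high == 7.0

    def test_linear_interpolation_quartiles(self):
        s = ms.steady_state_summary(list(range(1, 9)))
        assert s.median == pytest.approx(4.5)
        assert s.Q1 == pytest.approx(2.75)
        assert s.Q3 == pytest.approx(6.25)

    def test_reordering_invariance(self):
        vals = [3.0, 9.0, 1.0, 7.0, 5.0]
        assert ms.steady_state_summary(vals) == ms.steady_state_summary(sorted(vals))

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=10))
    def test_box_whisker_ordering_invariant(self, vals):
        s = ms.steady_state_summary(vals)
        assert s.min <= s.whisker_low <= s.Q1 <= s.median <= s.Q3 <= s.whisker_high <= s.max

    def test_window_selection(self):
        s = ms.steady_state_summary(
            [1.0, 2.0, 3.0, 4.0, 99.0], times=[0, 1, 2, 3, 10], window=(0, 5)
        )
        assert s.max == 4.0

    def test_too_few_samples(self):
        with pytest.raises(DomainError):
            ms.steady_state_summary([1.0, 2.0, 3.0])
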