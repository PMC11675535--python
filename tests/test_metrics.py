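import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lmspeed import metrics
from lmspeed.io import CellRecording, EpochSchedule, Trial, Protocol
from lmspeed.metrics import DirectionResponse

DIRS = np.arange(0.0, 360.0, 45.0)


def resp(rates, speed=32.0, spont=0.0):
    rates = np.asarray(rates, dtype=float)
    return DirectionResponse(
        cell_id="c", speed=speed, directions=DIRS.copy(), mean_rate=rates,
        sweep_rates=[np.array([r]) for r in rates], spont=spont,
        n_sweeps=np.ones(8, dtype=int),
    )


def brute_force_vector_sum(rates):
    """Independent loop-based evaluation of the vector-sum formulas."""
    sx = cx = total = 0.0
    for theta, r in zip(DIRS, rates):
        r = max(float(r), 0.0)
        sx += r * math.sin(math.radians(theta))
        cx += r * math.cos(math.radians(theta))
        total += r
    pd = math.degrees(math.atan2(sx, cx)) % 360.0 if total > 0 else math.nan
    si = math.hypot(sx, cx) / total if total > 0 else math.nan
    return pd, si


class TestPreferredDirection:
    def test_one_hot_returns_that_direction(self):
        assert metrics.preferred_direction(resp([0, 0, 9, 0, 0, 0, 0, 0])) == 90.0

    def test_two_equal_rates_bisect(self):
        r = resp([5, 0, 5, 0, 0, 0, 0, 0])
        assert metrics.preferred_direction(r) == pytest.approx(45.0)

    def test_matches_brute_force_oracle(self):
        rates = [20, 10, 0, 0, 0, 0, 0, 0]
        expected_pd, _ = brute_force_vector_sum(rates)
        assert metrics.preferred_direction(resp(rates)) == pytest.approx(
            expected_pd, abs=1e-9
        )

    def test_all_nonpositive_rates_flagged_undefined(self):
        assert math.isnan(metrics.preferred_direction(resp([-1.0] * 8)))


class TestSensitivityIndex:
    def test_uniform_response_is_exactly_zero(self):
        assert metrics.sensitivity_index(resp([7.0] * 8)) == 0.0

    def test_one_hot_response_is_exactly_one(self):
        assert metrics.sensitivity_index(resp([0, 0, 9, 0, 0, 0, 0, 0])) == 1.0

    def test_opposing_pair_cancels(self):
        # why bidirectional cells need the peak count: SI alone is blind
        assert metrics.sensitivity_index(resp([5, 0, 0, 0, 5, 0, 0, 0])) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.0, 100.0), min_size=8, max_size=8))
    def test_bounded_and_scale_invariant(self, rates):
        r = resp(rates)
        si = metrics.sensitivity_index(r)
        if math.isnan(si):
            return
        assert 0.0 <= si <= 1.0
        assert metrics.sensitivity_index(resp(np.array(rates) * 3.7)) == pytest.approx(
            si, abs=1e-12
        )

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.1, 50.0), min_size=8, max_size=8),
           st.sampled_from([45.0, 90.0, 135.0, 180.0]))
    def test_pd_equivariant_under_rotation(self, rates, delta):
        from hypothesis import assume

        # a balanced curve has no preferred direction: equivariance is vacuous
        assume(metrics.sensitivity_index(resp(rates)) > 1e-6)
        base = metrics.preferred_direction(resp(rates))
        rotated = DirectionResponse(
            cell_id="c", speed=32.0, directions=(DIRS + delta) % 360.0,
            mean_rate=np.asarray(rates), sweep_rates=[np.array([r]) for r in rates],
            spont=0.0, n_sweeps=np.ones(8, dtype=int),
        )
        expected = (base + delta) % 360.0
        got = metrics.preferred_direction(rotated)
        assert metrics.circ_dist(got, expected) < 1e-6


class TestApPd:
    def test_one_hot_cell_is_zero(self):
        assert metrics.ap_pd_ratio(resp([0, 0, 9, 0, 0, 0, 0, 0]), 90.0) == 0.0

    def test_symmetric_bidirectional_is_one(self):
        r = resp([8, 0, 0, 0, 8, 0, 0, 0])
        assert metrics.ap_pd_ratio(r, 0.0) == 1.0

    def test_half_rate_opposite(self):
        r = resp([20, 0, 0, 0, 10, 0, 0, 0])
        assert metrics.ap_pd_ratio(r, 0.0) == 0.5

    def test_undefined_when_pd_rate_nonpositive(self):
        assert math.isnan(metrics.ap_pd_ratio(resp([0.0] * 8), 0.0))


class TestInverseCV:
    def test_flat_curve_flagged_infinite(self):
        assert metrics.inverse_cv(resp([4.0] * 8)) == math.inf

    def test_single_direction_value(self):
        r = resp([20, 0, 0, 0, 0, 0, 0, 0])
        assert metrics.inverse_cv(r) == pytest.approx(2.5 / math.sqrt(50.0))

    def test_scale_invariance(self, rng):
        rates = rng.uniform(1, 30, 8)
        a = metrics.inverse_cv(resp(rates))
        b = metrics.inverse_cv(resp(rates * 5.0))
        assert a == pytest.approx(b)


class TestSplineAndPeaks:
    def test_constant_input_gives_constant_curve_zero_peaks(self):
        _, curve = metrics.fit_tuning_spline(DIRS, np.full(8, 5.0), df=8)
        assert np.allclose(curve, 5.0, atol=1e-8)
        assert metrics.peak_count(curve) == 0

    def test_near_interpolation_at_df8(self, rng):
        rates = rng.uniform(0, 30, 8)
        grid, curve = metrics.fit_tuning_spline(DIRS, rates, df=8)
        np.testing.assert_allclose(curve[::45], rates, atol=1e-6)

    def test_unimodal_input_gives_single_peak(self):
        rates = 20 * np.exp(4.0 * (np.cos(np.deg2rad(DIRS - 135.0)) - 1.0))
        _, curve = metrics.fit_tuning_spline(DIRS, rates, df=8)
        assert metrics.peak_count(curve) == 1

    def test_two_opposite_bumps_give_two_peaks(self):
        rates = np.exp(4.0 * (np.cos(np.deg2rad(DIRS - 90)) - 1.0)) + np.exp(
            4.0 * (np.cos(np.deg2rad(DIRS - 270)) - 1.0)
        )
        _, curve = metrics.fit_tuning_spline(DIRS, rates * 15, df=8)
        assert metrics.peak_count(curve) == 2

    def test_subthreshold_ripple_not_counted(self):
        curve = np.full(360, 10.0)
        curve += 0.05 * np.sin(np.deg2rad(np.arange(360) * 3))  # 3 tiny ripples
        curve[180] = 11.0  # one prominent peak sets the range
        assert metrics.peak_count(curve) == 1


def _recording_with_counts(counts_by_speed):
    """Deterministic recording: per speed, same spike count in every trial."""
    from lmspeed.io import DENSE_PROTOCOL

    trials, spikes = [], []
    schedule = EpochSchedule()
    for k, (sf, tf, count) in enumerate(counts_by_speed):
        for d in DIRS:
            t = Trial(trial_id=f"t{k}-{d}", direction=d, spatial_frequency=sf,
                      temporal_frequency=tf, sweep_index=1, schedule=schedule)
            trials.append(t)
            spikes.append(np.linspace(2.0, 4.99, count) if count else np.array([]))
    return CellRecording(cell_id="det", trials=trials, spikes=spikes,
                         protocol=DENSE_PROTOCOL)


class TestSpontaneousAndMostActive:
    def test_five_spikes_in_half_second_window_is_ten(self):
        schedule = EpochSchedule()
        trials = [Trial(trial_id="t", direction=0.0, spatial_frequency=0.25,
                        temporal_frequency=8.0, sweep_index=1, schedule=schedule)]
        spikes = [np.array([1.5, 1.6, 1.7, 1.8, 1.9])]
        cell = CellRecording(cell_id="c", trials=trials, spikes=spikes)
        assert metrics.spontaneous_rate(cell) == 10.0

    def test_silent_cell_rate_zero(self):
        cell = _recording_with_counts([(0.25, 8.0, 0)])
        assert metrics.spontaneous_rate(cell) == 0.0

    def test_tie_breaks_toward_slower_speed(self):
        # identical responses at 8 and 32 deg/s -> the slower one wins
        cell = _recording_with_counts([(0.25, 8.0, 12), (0.25, 2.0, 12)])
        assert metrics.most_active_speed(cell) == 8.0

    def test_single_speed_recording_returns_it(self):
        cell = _recording_with_counts([(0.25, 8.0, 9)])
        assert metrics.most_active_speed(cell) == 32.0


class TestOnSimulatedCells:
    def test_pd_recovered_within_sampling_step(self, archetype_cells):
        cell, truth = archetype_cells["directional"]
        r = metrics.direction_response(cell, 32.0)
        assert metrics.circ_dist(metrics.preferred_direction(r), truth.pd) <= 45.0

    def test_spontaneous_estimate_near_truth(self, archetype_cells):
        cell, truth = archetype_cells["directional"]
        spont = truth.params.spont
        n = len(cell.trials)
        se = math.sqrt(spont / 0.5 / n)  # Poisson rate SE over 0.5 s windows
        assert abs(metrics.spontaneous_rate(cell) - spont) < 3 * se

    def test_most_active_speed_matches_generator_center(self, archetype_cells):
        cell, truth = archetype_cells["directional"]
        best = metrics.most_active_speed(cell)
        assert abs(math.log2(best / truth.params.speed_center)) <= 1.0
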