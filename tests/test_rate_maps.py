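import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqdecode import (
    NeuronTuning,
    RateMap,
    SynthConfig,
    binned_counts,
    estimate_rates,
    mask_by_port,
    occupancy_map,
    peak_times,
    simulate_session,
    smooth_rates,
    sort_by_peak,
    zscore_rates,
)
from seqdecode.rate_maps import average_occupancy, gaussian_kernel
from seqdecode.session_model import TrackingTrace


def _map(rates, bin_width=0.05, t0=0.0, **kw):
    rates = np.atleast_2d(np.asarray(rates, float))
    return RateMap(
        [f"u{i}" for i in range(rates.shape[0])],
        "sample_press",
        (t0, t0 + rates.shape[1] * bin_width),
        bin_width,
        rates,
        **kw,
    )


class TestEstimateRates:
    def test_silent_unit_gives_zero_map(self, null_session):
        session, _ = null_session
        session = session  # type: ignore[assignment]
        from seqdecode.session_model import SpikeTrain

        session2 = session
        old = session2.units[0]
        session2.units[0] = SpikeTrain(old.unit_id, np.array([]))
        try:
            rm = estimate_rates(session2, units=[old.unit_id], delays=(10.0,), window=(0, 5))
            assert np.all(rm.rates == 0)
        finally:
            session2.units[0] = old

    def test_single_spike_single_trial_rate_arithmetic(self):
        import pandas as pd

        from seqdecode.session_model import Session, SpikeTrain, TrialTable

        row = dict(
            trial_index=0, sample_side="left", delay_s=1.0,
            t_sample_present=4.0, t_sample_press=5.0, t_port_on=6.0,
            t_nose_poke=6.2, t_choice_press=7.0, t_reward_entry=8.0, outcome="correct",
        )
        t = np.arange(0, 12, 1 / 30)
        tracking = TrackingTrace.from_positions(
            t, np.full(t.size, 1.0), np.full(t.size, 1.0), np.zeros(t.size)
        )
        # a spike exactly at the aligning event falls in the bin containing 0
        sess = Session(
            TrialTable(pd.DataFrame([row])), [SpikeTrain("a", np.array([5.0]))], tracking
        )
        rm = estimate_rates(sess, align_event="sample_press", window=(-1, 1),
                            bin_width_s=0.05, condition="left", outcomes=None)
        assert rm.rates.sum() == pytest.approx(20.0)
        assert rm.rates[0, 20] == pytest.approx(20.0)

    def test_homogeneous_rate_recovered_within_ci(self):
        cfg = SynthConfig(n_trials=200, delay_set=(10.0,), omission_rate=0.0, abort_rate=0.0,
                          tunings=[NeuronTuning(baseline_hz=10.0)], seed=1)
        session, _ = simulate_session(cfg)
        rm = estimate_rates(session, window=(0, 10), bin_width_s=0.05, delays=(10.0,))
        n_tr = sum(rm.n_trials.values())
        # per-bin 99% Poisson CI around 10 Hz
        lo, hi = stats.poisson.interval(0.999, 10.0 * n_tr * 0.05)
        assert rm.rates.min() >= lo / (n_tr * 0.05)
        assert rm.rates.max() <= hi / (n_tr * 0.05)

    def test_pooled_is_mean_of_side_psths(self, early_session):
        session, _ = early_session
        kw = dict(delays=(10.0,), window=(0, 4), bin_width_s=0.1)
        pooled = estimate_rates(session, **kw)
        left = estimate_rates(session, condition="left", **kw)
        right = estimate_rates(session, condition="right", **kw)
        assert np.allclose(pooled.rates, (left.rates + right.rates) / 2)

    def test_no_qualifying_trials_raises_with_condition(self, early_session):
        session, _ = early_session
        with pytest.raises(ValueError, match="left"):
            estimate_rates(session, delays=(99.0,), condition="left")


class TestSmoothing:
    def test_constant_row_unchanged(self):
        rm = smooth_rates(_map(np.full(100, 4.0)))
        assert np.allclose(rm.rates, 4.0)

    def test_impulse_response_is_gaussian(self):
        row = np.zeros(201)
        row[100] = 1.0
        rm = smooth_rates(_map(row), sigma_s=1 / 6)
        k = gaussian_kernel(1 / 6, 0.05)
        half = len(k) // 2
        assert np.allclose(rm.rates[0, 100 - half : 100 + half + 1], k)

    def test_matches_naive_convolution_oracle(self, rng):
        row = rng.uniform(0, 10, 120)
        rm = smooth_rates(_map(row), sigma_s=0.2)
        k = gaussian_kernel(0.2, 0.05)
        half = len(k) // 2
        # direct O(n^2) summation with edge renormalization
        expected = np.empty(row.size)
        for i in range(row.size):
            num = den = 0.0
            for j, kv in enumerate(k):
                idx = i + j - half
                if 0 <= idx < row.size:
                    num += kv * row[idx]
                    den += kv
            expected[i] = num / den
        assert np.allclose(rm.rates[0], expected, atol=1e-10)

    def test_mass_conserved_for_interior_signals(self, rng):
        row = np.zeros(400)
        row[150:250] = rng.uniform(0, 5, 100)
        rm = smooth_rates(_map(row))
        assert rm.rates.sum() == pytest.approx(row.sum(), rel=1e-6)

    def test_bin_wider_than_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            smooth_rates(_map(np.ones(10), bin_width=0.5), sigma_s=0.1)


class TestZScore:
    def test_constant_row_maps_to_zeros(self):
        z = zscore_rates(_map(np.full(50, 3.0), t0=-1.25))
        assert np.all(z.rates == 0)

    def test_zscore_arithmetic(self):
        row = np.array([5.0, 3.0, 7.0, 5.0, 9.0])  # mean 5.8, some sd
        z = zscore_rates(_map(row, t0=-0.125))
        assert np.allclose(z.rates[0], (row - row.mean()) / row.std())

    def test_invariant_to_constant_offset_after_smoothing(self, rng):
        row = rng.uniform(0, 5, 200)
        a = zscore_rates(smooth_rates(_map(row, t0=-5)))
        b = zscore_rates(smooth_rates(_map(row + 7.0, t0=-5)))
        assert np.allclose(a.rates, b.rates, atol=1e-10)


class TestPeaks:
    def test_monotone_ramp_peaks_at_last_bin(self):
        rm = _map(np.arange(10.0))
        assert peak_times(rm, (0, 0.5))[0] == pytest.approx(rm.bin_centers[-1])

    def test_tie_resolves_to_earlier_bin(self):
        row = np.zeros(10)
        row[[3, 7]] = 5.0
        rm = _map(row)
        assert peak_times(rm, (0, 0.5))[0] == pytest.approx(rm.bin_centers[3])

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="window"):
            peak_times(_map(np.ones(10)), (5.0, 6.0))

    def test_sort_by_peak_orders_matrix(self):
        rates = np.array([[0, 0, 1.0], [1.0, 0, 0], [0, 1.0, 0]])
        rm = _map(rates)
        peaks = peak_times(rm, (0, 0.15))
        order, sorted_rates = sort_by_peak(rm, peaks)
        assert list(order) == [1, 2, 0]
        assert np.allclose(np.argmax(sorted_rates, axis=1), [0, 1, 2])

    def test_planted_sequence_gives_diagonal_ridge(self, seq_session):
        session, truth = seq_session
        rm = smooth_rates(
            estimate_rates(session, delays=(10.0,), window=(-1, 11), bin_width_s=0.1)
        )
        peaks = peak_times(rm, (-1, 11))
        planted = np.array([t.seq_peak_time_s for t in truth.tunings])
        order, sorted_rates = sort_by_peak(rm, peaks)
        assert np.all(np.diff(planted[order]) >= 0)  # recovered order == planted order
        ridge_bins = np.argmax(sorted_rates, axis=1)
        assert np.all(np.diff(ridge_bins) >= 0)


class TestPortMask:
    def test_always_at_port_equals_unmasked(self):
        # rat pinned at port: in-port estimate must equal the plain PSTH
        cfg = SynthConfig(n_trials=60, delay_set=(5.0,), omission_rate=0.0, abort_rate=0.0,
                          jitter_in=0.0, tunings=[NeuronTuning(baseline_hz=5.0)], seed=2)
        session, _ = simulate_session(cfg)
        # pin the trajectory to the port
        tr = session.tracking
        pinned = TrackingTrace.from_positions(
            tr.t_s, np.full(tr.t_s.size, 4.75), np.full(tr.t_s.size, 0.5),
            np.zeros(tr.t_s.size),
        )
        session.tracking = pinned
        kw = dict(delays=(5.0,), window=(0, 5), bin_width_s=0.1, min_trials_per_side=1)
        masked = mask_by_port(session, **kw)
        plain = estimate_rates(session, delays=(5.0,), window=(0, 5), bin_width_s=0.1)
        assert masked.mask.all()
        assert np.allclose(masked.rates, plain.rates, atol=1e-9)

    def test_never_at_port_fully_masked(self):
        cfg = SynthConfig(n_trials=40, delay_set=(5.0,), omission_rate=0.0, abort_rate=0.0,
                          tunings=[NeuronTuning(baseline_hz=5.0)], seed=3)
        session, _ = simulate_session(cfg)
        pokes = session.trials.df["t_nose_poke"].dropna().to_numpy()
        # fake epochs far outside any trial window
        epochs = np.array([[session.duration_s - 0.5, session.duration_s - 0.4]])
        rm = mask_by_port(session, delays=(5.0,), window=(0, 5), bin_width_s=0.1,
                          port_epochs=epochs, min_trials_per_side=1)
        assert not rm.mask.any()


class TestOccupancy:
    def test_stationary_rat_single_tile(self):
        t = np.arange(0, 10, 1 / 30)
        tr = TrackingTrace.from_positions(
            t, np.full(t.size, 1.2), np.full(t.size, 2.2), np.zeros(t.size)
        )
        m = occupancy_map(tr, [(0, 10)])
        assert m.proportions.shape == (19, 24)
        assert m.proportions.max() == pytest.approx(1.0)
        assert m.proportions.sum() == pytest.approx(1.0)

    def test_uniform_positions_near_uniform_map(self, rng):
        n = 60000
        t = np.arange(n) / 30
        tr = TrackingTrace.from_positions(
            t, rng.uniform(0, 9.5, n), rng.uniform(0, 12, n), np.zeros(n)
        )
        m = occupancy_map(tr, [(0, t[-1] + 1)])
        counts = m.proportions * n
        chi2 = ((counts - n / counts.size) ** 2 / (n / counts.size)).sum()
        assert stats.chi2.sf(chi2, counts.size - 1) > 0.01

    def test_average_preserves_normalization(self, rng):
        maps = []
        for _ in range(3):
            n = 500
            t = np.arange(n) / 30
            tr = TrackingTrace.from_positions(
                t, rng.uniform(0, 9.5, n), rng.uniform(0, 12, n), np.zeros(n)
            )
            maps.append(occupancy_map(tr, [(0, t[-1] + 1)]))
        avg = average_occupancy(maps)
        assert avg.proportions.sum() == pytest.approx(1.0)
        assert avg.n_averaged == 3
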