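import numpy as np
import pytest
from scipy import stats

from seqdecode import (
    condition_rate_models,
    info_trace,
    info_vs_rate_peak_comparison,
    mi_at_time,
    mi_exact,
    pointwise_mi,
    press_info,
    shuffle_significance,
)
from seqdecode.sample_info import (
    UnitInfoModel,
    _mc_mi,
    press_context_dispersion,
    trace_centers,
)


class TestPointwiseMI:
    def test_equal_rates_give_exactly_zero(self, rng):
        lam = rng.uniform(0, 10, 10)
        s = rng.poisson(lam * 0.05)
        assert pointwise_mi(s, lam, lam, "left") == 0.0

    def test_matches_hand_computed_closed_form(self):
        # lambda_left = 2 Hz, lambda_right = 8 Hz, one spike in the first bin
        s = np.zeros(10)
        s[0] = 1
        lam_l, lam_r = np.full(10, 2.0), np.full(10, 8.0)
        dt = 0.05
        p_l = np.exp(-2 * dt * 10) * 2 * dt
        p_r = np.exp(-8 * dt * 10) * 8 * dt
        expected = np.log2(p_l / (0.5 * p_l + 0.5 * p_r))
        assert pointwise_mi(s, lam_l, lam_r, "left") == pytest.approx(expected)

    def test_bounded_below_one_bit(self):
        # heavily diagnostic sequence approaches but never exceeds 1 bit
        s = np.full(10, 5)
        val = pointwise_mi(s, np.full(10, 0.0), np.full(10, 40.0), "right")
        assert 0.9 < val <= 1.0 + 1e-9

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pointwise_mi(np.array([-1]), np.ones(1), np.ones(1), "left")


class TestMonteCarloEstimator:
    def test_equal_rate_model_estimates_zero(self, rng):
        lam = rng.uniform(0, 10, 10)
        mi, se = _mc_mi(lam, lam, 500, rng)
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_matches_brute_force(self, rng):
        lam_l, lam_r = np.array([1.0]), np.array([20.0])
        exact = mi_exact(lam_l, lam_r)
        mi, se = _mc_mi(lam_l, lam_r, 20000, rng)
        assert mi == pytest.approx(exact, abs=max(2.5 * se, 0.01))

    def test_fully_separating_model_approaches_one_bit(self, rng):
        lam_l, lam_r = np.zeros(3), np.full(3, 40.0)
        exact = mi_exact(lam_l, lam_r, max_count=30)
        mi, _ = _mc_mi(lam_l, lam_r, 20000, rng)
        assert exact > 0.98
        assert abs(mi - exact) < 0.02

    def test_relabeling_symmetry(self, rng):
        lam_l, lam_r = rng.uniform(0, 10, 3), rng.uniform(0, 10, 3)
        a = mi_exact(lam_l, lam_r, max_count=25)
        b = mi_exact(lam_r, lam_l, max_count=25)
        assert a == pytest.approx(b, abs=1e-12)

    def test_estimator_respects_one_bit_bound(self, rng):
        for _ in range(5):
            lam_l = rng.uniform(0, 30, 10)
            lam_r = rng.uniform(0, 30, 10)
            mi, _ = _mc_mi(lam_l, lam_r, 2000, rng)
            assert -0.05 <= mi <= 1.0


class TestConditionModels:
    def test_sides_with_identical_rates_fit_identically(self, rng):
        events = np.arange(20) * 30.0 + 10.0
        labels = np.array(["left", "right"] * 10)
        spikes = np.sort(rng.uniform(0, 650, 3000))
        m = UnitInfoModel(spikes, events, labels, (-1, 11))
        lam_l, lam_r = m.rates()
        # same homogeneous process on both sides: rates agree within noise
        assert abs(lam_l.mean() - lam_r.mean()) < 1.0
        assert np.all(lam_l >= 0) and np.all(lam_r >= 0)

    def test_planted_gain_recovered(self, early_session):
        session, truth = early_session
        i, tuning = next(
            (i, t) for i, t in enumerate(truth.tunings) if t.preferred_side == "right"
        )
        m = condition_rate_models(session, f"u{i:03d}", delays=(10.0,))
        lam_l, lam_r = m.rates()
        e0, e1 = tuning.selectivity_envelope
        sel = (m.bin_centers > e0 + 0.3) & (m.bin_centers < e1 - 0.3)
        ratio = lam_r[sel].mean() / max(lam_l[sel].mean(), 1e-9)
        assert ratio == pytest.approx(tuning.selectivity_gain, rel=0.35)

    def test_too_few_trials_per_side_raises(self, rng):
        events = np.array([1.0, 2.0, 3.0])
        labels = np.array(["left", "left", "left"])
        with pytest.raises(ValueError, match="per side"):
            UnitInfoModel(rng.uniform(0, 5, 10), events, labels, (0, 1))


class TestInfoTrace:
    def test_trace_length_formula(self):
        assert trace_centers((0, 10), 0.5, 0.05).size == int((10 - 0.5) / 0.05) + 1
        assert trace_centers((0, 1), 0.5, 0.25).size == 3

    def test_early_encoding_peak_inside_planted_envelope(self, early_session, rng):
        session, truth = early_session
        tr = info_trace(session, "u000", delays=(10.0,), stride_s=0.1, n_mc=300, rng=rng)
        e0, e1 = truth.tunings[0].selectivity_envelope
        assert e0 - 0.3 <= tr.peak_time_s <= e1 + 0.3
        assert tr.peak_bits > 0.1

    def test_null_trace_fluctuates_near_zero(self, null_session, rng):
        session, _ = null_session
        tr = info_trace(session, "u001", delays=(10.0,), stride_s=0.25, n_mc=300, rng=rng)
        assert np.max(np.abs(tr.mi_bits)) < 0.2

    def test_identity_permutation_reproduces_observed_peak(self, null_session, rng):
        session, _ = null_session
        m = condition_rate_models(session, "u000", delays=(10.0,), window=(-1, 11))
        centers = trace_centers((0, 10), 0.5, 0.5)
        from seqdecode.sample_info import _trace

        rng_a = np.random.default_rng(99)
        rng_b = np.random.default_rng(99)
        mi_obs, _ = _trace(m, centers, 200, rng_a, 0.5)
        mi_idperm, _ = _trace(m, centers, 200, rng_b, 0.5, labels=m.labels.copy())
        assert np.allclose(mi_obs, mi_idperm)

    def test_shuffle_flags_planted_encoding(self, early_session, rng):
        session, _ = early_session
        tr = shuffle_significance(
            session, "u002", n_shuffles=100, rng=rng, delays=(10.0,),
            stride_s=0.25, n_mc=200,
        )
        assert tr.significant
        assert tr.p < 0.02
        assert tr.null_peak_99 < tr.peak_bits


class TestPressInfo:
    def test_silent_unit_has_zero_information(self, null_session, rng):
        session, _ = null_session
        from seqdecode.session_model import SpikeTrain

        old = session.units[2]
        session.units[2] = SpikeTrain(old.unit_id, np.array([]))
        try:
            bits = press_info(session, old.unit_id, "sample", n_mc=200, rng=rng)
            assert bits == pytest.approx(0.0, abs=1e-9)
        finally:
            session.units[2] = old

    def test_choice_encoding_has_more_choice_than_sample_info(self, rng):
        from seqdecode import make_preset_session

        session, _ = make_preset_session(
            "choice_encoding", seed=23, n_units=4, n_trials=200, keep_rates=False
        )
        sample_bits = [press_info(session, u, "sample", 300, rng) for u in session.unit_ids]
        choice_bits = [press_info(session, u, "choice", 300, rng) for u in session.unit_ids]
        assert np.mean(choice_bits) > np.mean(sample_bits)

    def test_degenerate_dispersion_test_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            press_context_dispersion(np.ones(5), np.ones(7))

    def test_dispersion_f_test_detects_planted_split(self, rng):
        real = np.r_[rng.normal(0.4, 0.05, 20), rng.normal(-0.4, 0.05, 20)]
        shuf = rng.normal(0, 0.05, 200)
        F, p = press_context_dispersion(real, shuf)
        assert F > 1
        assert p < 1e-3

    def test_dispersion_f_test_calibrated_under_null(self, rng):
        ps = []
        for _ in range(200):
            a = rng.normal(0, 1, 25)
            b = rng.normal(0, 1, 25)
            ps.append(press_context_dispersion(a, b)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestDissociationStats:
    def test_identical_peaks_r_one_no_bias(self):
        peaks = np.linspace(0, 10, 20)
        r, p_corr, p_signed = info_vs_rate_peak_comparison(peaks, peaks)
        assert r == pytest.approx(1.0)
        assert p_signed == pytest.approx(1.0)

    def test_earlier_info_peaks_detected(self, rng):
        rate_peaks = rng.uniform(3, 10, 50)
        info_peaks = rate_peaks - 3.0
        _, _, p_signed = info_vs_rate_peak_comparison(info_peaks, rate_peaks)
        assert p_signed < 0.01

    def test_independent_peaks_weakly_correlated(self, rng):
        rs = [
            info_vs_rate_peak_comparison(rng.uniform(0, 10, 100), rng.uniform(0, 10, 100))[0]
            for _ in range(20)
        ]
        assert np.mean(np.abs(rs)) < 0.15
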