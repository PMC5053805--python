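import itertools

import numpy as np
import pytest
from scipy import stats

from seqdecode import (
    PoissonPopulationDecoder,
    build_pseudo_trials,
    decode_window,
    error_trial_trace,
    loo_accuracy_trace,
    make_preset_session,
)

DT = 0.05


def _bayes_side(S, lam_l, lam_r, dt=DT):
    ll_l = (S * np.log(lam_l * dt)).sum() - (lam_l * dt).sum()
    ll_r = (S * np.log(lam_r * dt)).sum() - (lam_r * dt).sum()
    if ll_l == ll_r:
        return None
    return "left" if ll_l > ll_r else "right"


class TestDecodeWindow:
    def test_agrees_with_enumerated_bayes_rule(self, rng):
        for _ in range(4):
            n, k = int(rng.integers(1, 3)), int(rng.integers(1, 4))
            lam_l = rng.uniform(0.5, 15, (n, k))
            lam_r = rng.uniform(0.5, 15, (n, k))
            for cfg in itertools.product(range(4), repeat=n * k):
                S = np.array(cfg).reshape(n, k)
                expected = _bayes_side(S, lam_l, lam_r)
                if expected is None:
                    continue
                assert decode_window(S, lam_l, lam_r, rng=rng) == expected

    def test_single_unit_threshold_on_total_count(self, rng):
        # constant rates: the ML rule reduces to a threshold on the total count
        lam_l, lam_r = np.full((1, 10), 1.0), np.full((1, 10), 10.0)
        thr = (lam_r - lam_l).sum() * DT / (np.log(lam_r[0, 0]) - np.log(lam_l[0, 0]))
        for total in range(31):
            S = np.zeros((1, 10), dtype=int)
            S[0, : total % 10] = total // 10 + 1  # any arrangement; only sum matters
            S[0, total % 10 :] = total // 10
            expected = "right" if S.sum() > thr else "left"
            if S.sum() == thr:
                continue
            assert decode_window(S, lam_l, lam_r, rng=rng) == expected

    def test_equal_models_decode_at_chance(self, rng):
        lam = np.full((2, 10), 4.0)
        outcomes = [
            decode_window(rng.poisson(lam * DT), lam, lam, rng=rng) for _ in range(400)
        ]
        frac_left = np.mean([o == "left" for o in outcomes])
        assert 0.42 < frac_left < 0.58

    def test_left_right_relabeling_symmetry(self, rng):
        lam_l = rng.uniform(1, 10, (3, 10))
        lam_r = rng.uniform(1, 10, (3, 10))
        S = rng.poisson(lam_l * DT)
        a = decode_window(S, lam_l, lam_r, rng=rng)
        b = decode_window(S, lam_r, lam_l, rng=rng)
        assert {a, b} == {"left", "right"} or a != b

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            decode_window(np.zeros((2, 5), int), np.ones((2, 4)), np.ones((2, 4)))

    def test_population_accuracy_matches_enumerated_bayes(self, rng):
        # 2 units x 2 bins model: exact Bayes accuracy by enumeration
        lam_l = np.array([[2.0, 8.0], [6.0, 1.0]])
        lam_r = np.array([[7.0, 3.0], [1.0, 5.0]])
        cmax = 12
        acc_exact = 0.0
        for cfg in itertools.product(range(cmax), repeat=4):
            S = np.array(cfg).reshape(2, 2)
            p_l = np.prod(stats.poisson.pmf(S, lam_l * DT))
            p_r = np.prod(stats.poisson.pmf(S, lam_r * DT))
            acc_exact += 0.5 * max(p_l, p_r)
        n = 4000
        hits = 0
        for _ in range(n):
            side = "left" if rng.random() < 0.5 else "right"
            lam = lam_l if side == "left" else lam_r
            S = rng.poisson(lam * DT)
            hits += decode_window(S, lam_l, lam_r, rng=rng) == side
        lo, hi = stats.binom.interval(0.99, n, acc_exact)
        assert lo <= hits <= hi


class TestPseudoTrials:
    def test_single_available_trial_used_everywhere(self, early_session, rng):
        session, _ = early_session
        ps = build_pseudo_trials(session, condition=("left", "correct"), n=50, rng=rng)
        one_trial = ps.source_trials[:1]
        # restrict sources artificially: a unit with 1 trial contributes it always
        assert ps.assignments.shape == (50, len(session.units))
        assert ps.assignments.max() < ps.source_trials.size

    def test_sources_drawn_uniformly(self, early_session, rng):
        session, _ = early_session
        ps = build_pseudo_trials(session, condition=("right", "correct"), n=5000, rng=rng)
        counts = np.bincount(ps.assignments.ravel(), minlength=ps.source_trials.size)
        expected = ps.assignments.size / ps.source_trials.size
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, ps.source_trials.size - 1) > 0.01

    def test_empty_condition_raises(self, early_session, rng):
        session, _ = early_session
        with pytest.raises(ValueError, match="condition"):
            build_pseudo_trials(session, condition=("left", "correct"), delays=(42.0,), rng=rng)


class TestTraces:
    def test_loo_training_excludes_held_out_trial(self, early_session, rng):
        # structural check: the LOO rate for unit j with held-out trial t equals
        # the mean of the smoothed counts of all other trials
        session, _ = early_session
        dec = PoissonPopulationDecoder(model_window=(-1.0, 11.0))
        dec.fit(session, delays=(10.0,))
        side, j, t = "left", 0, 3
        n_tr = dec.counts_[side].shape[1]
        base = dec.counts_sm_[side][j].sum(axis=0)
        lam_loo = (base - dec.counts_sm_[side][j][t]) / ((n_tr - 1) * dec.bin_s)
        manual = np.delete(dec.counts_sm_[side][j], t, axis=0).mean(axis=0) / dec.bin_s
        assert np.allclose(lam_loo, manual)

    def test_label_shuffled_training_decodes_at_chance(self, rng):
        session, _ = make_preset_session(
            "early_encoding", seed=31, n_units=8, n_trials=200, keep_rates=False
        )
        # destroy the label information by shuffling sample sides
        df = session.trials.df
        df["sample_side"] = rng.permutation(df["sample_side"].to_numpy())
        trace = loo_accuracy_trace(session, delays=(10.0,), stride_s=1.0,
                                   n_pseudo=300, rng=rng)
        assert abs(trace.accuracy.mean() - 0.5) < 0.1

    def test_accuracy_bounded_and_sem_from_n_min(self, early_session, rng):
        session, _ = early_session
        trace = loo_accuracy_trace(session, delays=(10.0,), stride_s=2.0,
                                   n_pseudo=200, rng=rng)
        assert np.all((0 <= trace.accuracy) & (trace.accuracy <= 1))
        assert np.allclose(
            trace.sem_upper, np.sqrt(trace.accuracy * (1 - trace.accuracy) / trace.n_min)
        )

    def test_unit_order_invariance(self, early_session):
        session, _ = early_session
        a = loo_accuracy_trace(session, units=session.unit_ids, delays=(10.0,),
                               stride_s=2.0, n_pseudo=150, rng=np.random.default_rng(5))
        b = loo_accuracy_trace(session, units=session.unit_ids[::-1], delays=(10.0,),
                               stride_s=2.0, n_pseudo=150, rng=np.random.default_rng(5))
        # same trials, same seed, permuted units: accuracies statistically equal
        assert abs(a.accuracy.mean() - b.accuracy.mean()) < 0.08

    def test_no_error_trials_raises(self, rng):
        session, _ = make_preset_session(
            "null", seed=3, n_units=2, n_trials=30, keep_rates=False,
            p_correct={1.0: 1.0, 5.0: 1.0, 10.0: 1.0},
        )
        with pytest.raises(ValueError, match="error trials"):
            error_trial_trace(session, delays=(10.0,), rng=rng)
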