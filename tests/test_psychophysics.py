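"""Simulated observers, QUEST+ staircases, Weibull fits, delivery filter."""

import numpy as np
import pandas as pd
import pytest

from smallspot.exceptions import (
    InvalidInputError,
    InvalidParameterError,
    NonIdentifiableError,
)
from smallspot.psychophysics import (
    OFFSET_COLUMNS,
    PsychometricModel,
    QuestPlus,
    delivery_filter,
    fit_session,
    fit_weibull_threshold,
    run_questplus_block,
    simulate_delivery_offsets,
    simulate_detection_response,
)


class TestPsychometricModel:
    def test_threshold_closed_form(self):
        m = PsychometricModel(alpha=2.0, beta=2.0, gamma=0.0, lapse=0.0)
        assert m.threshold(0.5) == pytest.approx(2.0 * np.sqrt(np.log(2.0)))

    def test_half_seen_at_closed_form_intensity(self):
        m = PsychometricModel(alpha=1.3, beta=3.0, gamma=0.0, lapse=0.0)
        i50 = 1.3 * np.log(2.0) ** (1.0 / 3.0)
        assert m.p_seen(i50) == pytest.approx(0.5)
        rng = np.random.default_rng(0)
        draws = [simulate_detection_response(m, i50, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.02)

    def test_zero_intensity_never_seen_without_guessing(self):
        m = PsychometricModel(alpha=1.0, beta=3.0, gamma=0.0, lapse=0.0)
        rng = np.random.default_rng(1)
        assert not any(simulate_detection_response(m, 0.0, rng) for _ in range(100))

    def test_high_intensity_always_seen_without_lapse(self):
        m = PsychometricModel(alpha=1.0, beta=3.0, gamma=0.0, lapse=0.0)
        assert m.p_seen(1e6) == pytest.approx(1.0)

    def test_from_threshold50_round_trip(self):
        m = PsychometricModel.from_threshold50(0.02, 3.0, lapse=0.02)
        assert m.threshold(0.5) == pytest.approx(0.02)

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            PsychometricModel(alpha=0.0, beta=1.0)
        with pytest.raises(InvalidParameterError):
            PsychometricModel(alpha=1.0, beta=1.0, gamma=0.6, lapse=0.5)


class TestQuestPlus:
    def test_converges_to_steep_observer_threshold(self):
        obs = {("l", 543.0): PsychometricModel(alpha=0.02, beta=8.0, gamma=0.0, lapse=0.0)}
        sessions = run_questplus_block(obs, n_trials_per_staircase=40, catch_rate=0.0, seed=0)
        q = QuestPlus()
        for _, row in sessions[0].trials.iterrows():
            q.update(row["intensity"], row["seen"])
        grid_step = np.log10(q.intensities[1] / q.intensities[0])
        assert abs(np.log10(q.posterior_mode_alpha() / 0.02)) <= 1.5 * grid_step

    def test_catch_rate_zero_all_adaptive(self):
        obs = {("l", 543.0): PsychometricModel.from_threshold50(0.02, 3.0)}
        s = run_questplus_block(obs, n_trials_per_staircase=10, catch_rate=0.0, seed=1)[0]
        assert set(s.trials["source"]) == {"staircase"}

    def test_same_seed_identical_sequences(self):
        obs = {("l", 543.0): PsychometricModel.from_threshold50(0.02, 3.0),
               ("l", 680.0): PsychometricModel.from_threshold50(0.1, 3.0)}
        a = run_questplus_block(obs, seed=9)
        b = run_questplus_block(obs, seed=9)
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.trials, sb.trials)

    def test_staircase_trial_counts(self):
        obs = {("l", 543.0): PsychometricModel.from_threshold50(0.02, 3.0)}
        s = run_questplus_block(obs, n_trials_per_staircase=25, n_staircases=2,
                                catch_rate=0.2, seed=3)[0]
        assert len(s.trials) == 50
        frac_catch = (s.trials["source"] == "random_catch").mean()
        assert 0.05 < frac_catch < 0.4  # binomial around the 20% catch rate

    def test_posterior_entropy_decreases_for_matched_observer(self):
        drops = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            model = PsychometricModel(alpha=0.03, beta=3.0, gamma=0.0, lapse=0.02)
            q = QuestPlus()
            h0 = q.posterior_entropy()
            for _ in range(25):
                i = q.next_intensity()
                q.update(i, simulate_detection_response(model, i, rng))
            drops.append(h0 - q.posterior_entropy())
        assert np.mean(drops) > 1.0  # strong average information gain


class TestWeibullFit:
    def test_recovers_dense_noiseless_threshold(self):
        model = PsychometricModel(alpha=1.0, beta=3.0, gamma=0.0, lapse=0.0)
        i = np.geomspace(0.2, 3.0, 400)
        rng = np.random.default_rng(0)
        seen = rng.random(400) < model.p_seen(i)
        fit, thr, info = fit_weibull_threshold(i, seen, gamma=0.0, lapse=0.0)
        assert thr == pytest.approx(np.log(2.0) ** (1 / 3.0), rel=0.05)
        assert info["converged"]

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        model = PsychometricModel(alpha=0.05, beta=2.5)
        i = np.geomspace(0.005, 0.5, 200)
        seen = rng.random(200) < model.p_seen(i)
        _, thr1, _ = fit_weibull_threshold(i, seen)
        _, thr2, _ = fit_weibull_threshold(i * 7.0, seen)
        assert thr2 == pytest.approx(7.0 * thr1, rel=1e-3)

    def test_non_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            fit_weibull_threshold(np.ones(10), np.ones(10, dtype=bool))
        with pytest.raises(NonIdentifiableError):
            fit_weibull_threshold(np.ones(10), np.zeros(10, dtype=bool))

    def test_session_fit_recovery_sanity(self):
        errs = []
        for seed in range(5):
            obs = {("l", 543.0): PsychometricModel.from_threshold50(0.02, 3.0)}
            sess = run_questplus_block(obs, seed=seed)[0]
            fit_session(sess)
            errs.append(abs(np.log10(sess.threshold_50 / 0.02)))
        assert np.median(errs) < 0.1


class TestDeliveryFilter:
    def _frame(self, offsets):
        return pd.DataFrame(offsets, columns=OFFSET_COLUMNS)

    def test_all_zero_fully_included(self):
        df = self._frame(np.zeros((20, 6)))
        _, pct = delivery_filter(df)
        assert pct == 100.0

    def test_boundary_is_inclusive_and_excess_excluded(self):
        offsets = np.zeros((2, 6))
        offsets[0, 2] = 0.75   # exactly at criterion: kept
        offsets[1, 2] = 0.80   # one frame beyond: dropped
        included, pct = delivery_filter(self._frame(offsets))
        assert len(included) == 1 and pct == 50.0

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        off = simulate_delivery_offsets(500, rng, contamination_rate=0.15)
        df = self._frame(off)
        _, p1 = delivery_filter(df)
        _, p2 = delivery_filter(df.sample(frac=1.0, random_state=1))
        assert p1 == p2

    def test_empty(self):
        with pytest.raises(InvalidInputError):
            delivery_filter(pd.DataFrame(columns=OFFSET_COLUMNS))

    def test_gaussian_jitter_alone_rarely_excludes(self):
        rng = np.random.default_rng(4)
        off = simulate_delivery_offsets(2000, rng)
        _, pct = delivery_filter(self._frame(off))
        assert pct == 100.0
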