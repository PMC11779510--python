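"""Task simulator: schedules, staircases, race model, MVC and EMG synthesis."""

import math

import numpy as np
import pytest

from aristop import (EMGGenParams, RaceModelParams, RunConfig, SessionConfig,
                     StaircaseState, make_trial_schedule, simulate_cohort,
                     simulate_mvc, simulate_session, simulate_trial,
                     staircase_update, synth_emg_trial)
from aristop.errors import ConfigurationError, UsageError
from aristop import task_sim


class TestSchedule:
    def test_default_counts_exact(self):
        cfg = SessionConfig()
        sched = make_trial_schedule(cfg, np.random.default_rng(0))
        counts = {t: sched.count(t) for t in set(sched)}
        assert counts == {"go": 192, "stop_both": 32, "stop_left": 32,
                          "stop_right": 32}
        assert len(sched) == 288

    def test_small_schedule_counts_every_seed(self):
        cfg = SessionConfig(n_blocks=1, trials_per_block=6, go_fraction=0.5)
        for seed in range(20):
            sched = make_trial_schedule(cfg, np.random.default_rng(seed))
            assert sched.count("go") == 3
            for t in ("stop_both", "stop_left", "stop_right"):
                assert sched.count(t) == 1

    def test_seed_determinism(self):
        cfg = SessionConfig()
        a = make_trial_schedule(cfg, np.random.default_rng(42))
        b = make_trial_schedule(cfg, np.random.default_rng(42))
        c = make_trial_schedule(cfg, np.random.default_rng(43))
        assert a == b
        assert a != c  # 288-trial multinomial: collision essentially impossible

    def test_non_integral_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            SessionConfig(n_blocks=1, trials_per_block=7, go_fraction=0.5)


class TestStaircase:
    def make(self, **ssd):
        base = {"stop_both": -200.0, "stop_left": -250.0, "stop_right": -250.0}
        base.update(ssd)
        return StaircaseState(ssd=base, step=50.0)

    def test_failed_stop_moves_earlier(self):
        state = staircase_update(self.make(), "stop_both", "failed_stop")
        assert state.ssd["stop_both"] == -250.0
        assert state.ssd["stop_left"] == -250.0  # untouched

    def test_inverse_steps_cancel(self):
        state = self.make(stop_both=-250.0)
        state = staircase_update(state, "stop_both", "successful_stop")
        assert state.ssd["stop_both"] == -200.0
        state = staircase_update(state, "stop_both", "failed_stop")
        assert state.ssd["stop_both"] == -250.0

    def test_iterated_updates(self):
        state = self.make(stop_both=-250.0)
        expected = [-300.0, -350.0, -300.0]
        for outcome, want in zip(
                ["failed_stop", "failed_stop", "successful_stop"], expected):
            state = staircase_update(state, "stop_both", outcome)
            assert state.ssd["stop_both"] == want
        assert [h[3] for h in state.history] == expected

    def test_go_outcome_rejected(self):
        with pytest.raises(UsageError):
            staircase_update(self.make(), "stop_both", "go_response")
        with pytest.raises(UsageError):
            staircase_update(self.make(), "go", "failed_stop")


class TestRaceModel:
    cfg = SessionConfig()

    def test_unstoppable_stop_process_always_fails(self, rng):
        race = RaceModelParams(ssrt_mean=10_000.0, ssrt_sd=0.0)
        for _ in range(50):
            t = simulate_trial("stop_both", -200.0, race, rng, self.cfg)
            assert t.outcome == "failed_stop"

    def test_instant_stop_process_always_succeeds(self, rng):
        # stop signal far before any possible planned response
        race = RaceModelParams(ssrt_mean=0.0, ssrt_sd=0.0)
        for _ in range(50):
            t = simulate_trial("stop_both", -700.0, race, rng, self.cfg)
            assert t.outcome == "successful_stop"

    def test_failed_stop_probability_matches_normal_cdf(self, rng):
        # planned RT ~ N(800, 20), stop at 550, constant stop latency 240:
        # the cued hand responds iff RT < 790, p = Phi(-0.5) ~ 0.3085
        race = RaceModelParams(
            go_rt_mean={"left": 800.0, "right": 800.0}, go_rt_sd=20.0,
            ssrt_mean=240.0, ssrt_sd=0.0)
        n = 4000
        fails = sum(
            simulate_trial("stop_left", -250.0, race, rng, self.cfg)
            .outcome == "failed_stop" for _ in range(n))
        assert abs(fails / n - 0.3085) < 0.025

    def test_selective_trial_delays_continuing_hand(self, rng):
        race = RaceModelParams(go_rt_sd=1.0, ssrt_mean=0.0, ssrt_sd=0.0,
                               interference_delay_mean=95.0,
                               interference_delay_sd=1.0)
        t = simulate_trial("stop_left", -700.0, race, rng, self.cfg)
        assert t.response_time["left"] is None
        assert t.response_time["right"] == pytest.approx(
            race.go_rt_mean["right"] + 95.0, abs=10.0)

    def test_ssd_presence_contract(self, rng):
        race = RaceModelParams()
        with pytest.raises(UsageError):
            simulate_trial("go", -200.0, race, rng, self.cfg)
        with pytest.raises(UsageError):
            simulate_trial("stop_both", None, race, rng, self.cfg)


class TestMVC:
    def test_mean_of_four_maxima(self, monkeypatch):
        peaks = iter([2.0, 4.0, 6.0, 8.0])

        def fake_noise(n, fs, params, rng):
            out = np.zeros(n)
            out[n // 2] = next(peaks)
            return out

        monkeypatch.setattr(task_sim, "band_limited_noise", fake_noise)
        assert simulate_mvc(EMGGenParams(mvc_sd=1.0),
                            np.random.default_rng(0)) == pytest.approx(5.0)

    def test_seeded_determinism(self):
        p = EMGGenParams()
        a = simulate_mvc(p, np.random.default_rng(3))
        b = simulate_mvc(p, np.random.default_rng(3))
        assert a == b and a > 0


class TestEMGSynthesis:
    def make_trial(self, small_config, seed=5, want="stop_both"):
        session = simulate_session("s", small_config, seed)
        for t in session.trials:
            if t.trial_type == want:
                return session, t
        raise AssertionError

    def test_tonic_level_tracks_mvc_fraction(self, small_config):
        session, trial = self.make_trial(small_config, want="go")
        tr = session.emg_for_trial(trial.index, channels=("left_ADM",))["left_ADM"]
        expect = small_config.emg.tonic_fraction_mvc * session.mvc
        got = np.abs(tr.samples).mean()
        # response-coupled gain bump inflates the mean slightly
        assert got == pytest.approx(expect, rel=0.15)

    def test_rectified_mean_of_gaussian_noise(self, rng):
        # E|N(0, sigma)| = sigma * sqrt(2/pi), checked on the band-limited
        # carrier used by the generator
        x = task_sim.band_limited_noise(200_000, 5000.0, EMGGenParams(), rng)
        assert np.abs(x).mean() == pytest.approx(math.sqrt(2 / math.pi),
                                                 rel=0.02)

    def test_dip_halves_amplitude_in_window(self, small_config):
        session, trial = self.make_trial(small_config)
        fs = small_config.session.sampling_rate
        tr = session.emg_for_trial(trial.index, channels=("left_ADM",))["left_ADM"]
        lo, hi = trial.ground_truth["dip_window"]
        sl = slice(int(lo * fs / 1000) + 1, int(hi * fs / 1000) - 1)
        inside = np.abs(tr.samples[sl]).mean()
        pre = np.abs(tr.samples[:int((lo - 50) * fs / 1000)]).mean()
        assert inside / pre == pytest.approx(1.0 - small_config.emg.dip_depth,
                                             abs=0.1)

    def test_channel_subset_is_bit_identical(self, small_session):
        idx = 0
        full = small_session.emg_for_trial(idx)
        sub = small_session.emg_for_trial(idx, channels=("right_ADM",))
        np.testing.assert_array_equal(full["right_ADM"].samples,
                                      sub["right_ADM"].samples)

    def test_mvc_must_be_positive(self, small_config, rng):
        session, trial = self.make_trial(small_config)
        with pytest.raises(ConfigurationError):
            synth_emg_trial(trial, small_config.emg, 0.0, rng,
                            small_config.session)


class TestSessionsAndCohorts:
    def test_session_trial_count_and_blocks(self, small_session, small_config):
        assert len(small_session.trials) == small_config.session.n_trials
        blocks = {t.block for t in small_session.trials}
        assert blocks == set(range(small_config.session.n_blocks))

    def test_cohort_shape_and_seed_record(self, small_config):
        sessions = simulate_cohort(3, small_config, seed=9)
        assert len(sessions) == 3
        assert len({s.seed for s in sessions}) == 3
        for s in sessions:
            assert len(s.trials) == small_config.session.n_trials

    def test_cohort_determinism(self, small_config):
        a = simulate_cohort(2, small_config, seed=21)
        b = simulate_cohort(2, small_config, seed=21)
        for sa, sb in zip(a, b):
            assert sa.trials_df().equals(sb.trials_df())
            assert sa.mvc == sb.mvc
            np.testing.assert_array_equal(
                sa.emg_for_trial(4)["left_FDI"].samples,
                sb.emg_for_trial(4)["left_FDI"].samples)

    def test_stop_trials_record_dip_ground_truth(self, small_session):
        target = small_session.config.session.target_time
        lat = small_session.config.emg.dip_latency
        dur = small_session.config.emg.dip_duration
        for t in small_session.trials:
            if t.is_stop:
                lo, hi = t.ground_truth["dip_window"]
                assert lo == pytest.approx(t.stop_time(target) + lat)
                assert hi - lo == pytest.approx(dur)
            else:
                assert "dip_window" not in t.ground_truth
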