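import numpy as np
import pytest

from cohtms import (
    DspParams,
    MEPModel,
    PartialSessionError,
    SynthConfig,
    TriggerConfig,
    TriggerState,
    count_below_threshold,
    generate_eeg_pair,
    run_control_session,
    run_session,
    run_session_from_series,
    step,
)
from cohtms.trigger import draw_control_intervals


def make_cfg(**kw):
    defaults = dict(initial_threshold=0.660, n_stimuli=10)
    defaults.update(kw)
    return TriggerConfig(**defaults)


class TestStep:
    def test_maximal_coherence_always_fires_and_resets(self):
        cfg = make_cfg()
        state = TriggerState(current_threshold=0.4, seconds_since_last_stimulus=40)
        new, ev = step(state, 1.0, cfg, time=41.0)
        assert ev is not None
        assert ev.coh_at_stim == 1.0
        assert ev.threshold_at_stim == 0.4
        assert ev.modified  # threshold had decayed below the initial value
        assert new.current_threshold == cfg.initial_threshold
        assert new.seconds_since_last_stimulus == 0.0
        assert new.phase == "paused"

    def test_decay_law_closed_form(self):
        # never-firing stream: threshold(t) = max(0, th0 - 0.05*(t-30))
        cfg = make_cfg(threshold_floor=0.0)
        state = TriggerState.initial(cfg)
        for t in range(1, 50):
            state, ev = step(state, 0.0, cfg, time=float(t))
            expected = max(0.0, 0.660 - 0.05 * max(0, t - 30))
            if ev is not None:
                # fires at the first comparison against the fully decayed 0
                assert t == 45
                assert ev.threshold_at_stim == 0.0
                break
            assert state.current_threshold == pytest.approx(expected, abs=1e-12)
        else:
            pytest.fail("never fired")

    def test_no_decay_before_onset(self):
        cfg = make_cfg()
        state = TriggerState.initial(cfg)
        for t in range(1, 30):
            state, _ = step(state, 0.0, cfg, time=float(t))
        assert state.current_threshold == cfg.initial_threshold
        state, _ = step(state, 0.0, cfg, time=30.0)
        assert state.current_threshold == cfg.initial_threshold  # t=30: still none
        state, _ = step(state, 0.0, cfg, time=31.0)
        assert state.current_threshold == pytest.approx(0.660 - 0.05)

    def test_floor_respected(self):
        cfg = make_cfg(initial_threshold=0.9, threshold_floor=0.8)
        state = TriggerState.initial(cfg)
        for t in range(1, 60):
            state, ev = step(state, 0.0, cfg, time=float(t))
            assert ev is None  # floor 0.8 > 0 is never crossed by coh=0
        assert state.current_threshold == pytest.approx(0.8)

    def test_recharge_marker_at_standby_limit(self):
        cfg = make_cfg(initial_threshold=0.9, threshold_floor=0.8)
        state = TriggerState.initial(cfg)
        for t in range(1, 121):
            state, _ = step(state, 0.0, cfg, time=float(t))
        assert state.recharge_events == (60.0, 120.0)

    def test_step_while_paused_is_contract_violation(self):
        cfg = make_cfg()
        state, _ = step(TriggerState.initial(cfg), 1.0, cfg, time=1.0)
        assert state.phase == "paused"
        with pytest.raises(RuntimeError, match="paused"):
            step(state, 0.5, cfg, time=2.0)

    def test_out_of_range_coherence_rejected(self):
        cfg = make_cfg()
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            step(TriggerState.initial(cfg), 1.5, cfg)

    def test_disabled_modification_never_decays(self):
        cfg = make_cfg(modification_enabled=False)
        state = TriggerState.initial(cfg)
        for t in range(1, 200):
            state, _ = step(state, 0.0, cfg, time=float(t))
        assert state.current_threshold == cfg.initial_threshold


class TestConfigValidation:
    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            make_cfg(delta=0.0)

    def test_pause_must_precede_onset(self):
        with pytest.raises(ValueError, match="pause"):
            make_cfg(pause=35.0)

    def test_floor_above_threshold_rejected(self):
        with pytest.raises(ValueError):
            make_cfg(initial_threshold=0.3, threshold_floor=0.5)


class TestRunSession:
    def test_constant_unit_coherence_spacing_eleven_seconds(self, dsp_params):
        # a = 1: both channels identical, coh = 1 every tick; each section is
        # 1 analysis tick + 10 paused ticks
        cfg_s = SynthConfig(duration=120, mixing_mean=1.0, drift_amplitude=0.0, seed=2)
        ch1, ch2, _ = generate_eeg_pair(cfg_s)
        res = run_session(ch1, ch2, make_cfg(), MEPModel(seed=0), dsp_params)
        times = [e.time for e in res.events]
        assert times == [1.0 + 11.0 * i for i in range(10)]
        assert np.all(np.diff(times) == 11.0)
        assert res.total_time == times[-1]

    def test_trigger_condition_holds_for_every_event(self, dsp_params):
        cfg_s = SynthConfig(duration=700, seed=14)
        ch1, ch2, _ = generate_eeg_pair(cfg_s)
        res = run_session(ch1, ch2, make_cfg(initial_threshold=0.8),
                          MEPModel(seed=1), dsp_params)
        for e in res.events:
            assert e.coh_at_stim >= e.threshold_at_stim
            assert e.modified == (e.threshold_at_stim < 0.8)

    def test_no_two_events_closer_than_pause_plus_one(self, dsp_params):
        cfg_s = SynthConfig(duration=700, seed=15)
        ch1, ch2, _ = generate_eeg_pair(cfg_s)
        res = run_session(ch1, ch2, make_cfg(initial_threshold=0.85),
                          MEPModel(seed=1), dsp_params)
        assert np.diff([e.time for e in res.events]).min() >= 11.0

    def test_determinism_identical_runs(self, dsp_params):
        cfg_s = SynthConfig(duration=700, seed=16)
        ch1, ch2, _ = generate_eeg_pair(cfg_s)
        r1 = run_session(ch1, ch2, make_cfg(), MEPModel(seed=3), dsp_params,
                         rng=np.random.default_rng(9))
        r2 = run_session(ch1, ch2, make_cfg(), MEPModel(seed=3), dsp_params,
                         rng=np.random.default_rng(9))
        assert r1 == r2

    def test_liveness_bound_with_zero_floor(self):
        # coh = 0 forever; decay guarantees each section fires within
        # onset + th0/delta + pause + 1 seconds
        cfg = make_cfg()
        bound = cfg.n_stimuli * (cfg.modification_onset
                                 + cfg.initial_threshold / cfg.delta
                                 + cfg.pause + 1)
        series = np.zeros(int(bound))
        res = run_session_from_series(series, cfg, MEPModel(seed=0))
        assert len(res.events) == 10
        assert res.total_time <= bound

    def test_threshold_resets_each_section(self):
        cfg = make_cfg()
        series = np.zeros(600)
        res = run_session_from_series(series, cfg)
        # every stimulus on a coh=0 stream fires at the fully decayed
        # threshold after an identical section profile
        assert all(e.threshold_at_stim == 0.0 for e in res.events)
        intervals = np.diff([0.0] + [e.time for e in res.events])
        assert np.all(intervals[1:] == intervals[1])  # identical post-reset sections

    def test_exhausted_source_raises_partial(self, dsp_params):
        cfg_s = SynthConfig(duration=30, seed=17)
        ch1, ch2, _ = generate_eeg_pair(cfg_s)
        with pytest.raises(PartialSessionError) as exc:
            run_session(ch1, ch2, make_cfg(initial_threshold=1.0),
                        MEPModel(seed=0), dsp_params)
        assert isinstance(exc.value.events, tuple)

    def test_interval_bookkeeping(self):
        res = run_session_from_series(np.ones(40), make_cfg(n_stimuli=3),
                                      MEPModel(seed=0))
        times = [e.time for e in res.events]
        assert list(res.inter_stimulus_intervals) == list(np.diff([0.0] + times))
        assert len(res.inter_stimulus_intervals) == 3


class TestControlSession:
    def test_intervals_within_support_and_count(self, dsp_params):
        cfg_s = SynthConfig(duration=400, seed=18)
        ch1, ch2, _ = generate_eeg_pair(cfg_s)
        res = run_control_session(ch1, ch2, make_cfg(), MEPModel(seed=0),
                                  dsp_params, rng=np.random.default_rng(4))
        assert len(res.events) == 10
        ivals = np.asarray(res.inter_stimulus_intervals)
        assert np.all((ivals >= 25) & (ivals <= 35))
        assert res.total_time == pytest.approx(ivals.sum())
        assert res.condition == "random_control"

    def test_interval_mean_close_to_thirty(self):
        draws = draw_control_intervals(10_000, np.random.default_rng(0))
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 30.0) < 3 * se

    def test_integer_second_granularity(self):
        draws = draw_control_intervals(1000, np.random.default_rng(1))
        assert np.all(draws == np.round(draws))

    def test_short_record_raises_partial(self, dsp_params):
        cfg_s = SynthConfig(duration=60, seed=19)
        ch1, ch2, _ = generate_eeg_pair(cfg_s)
        with pytest.raises(PartialSessionError):
            run_control_session(ch1, ch2, make_cfg(), MEPModel(seed=0),
                                dsp_params, rng=np.random.default_rng(4))


class TestCountBelowThreshold:
    def test_nothing_below_zero(self):
        assert count_below_threshold(np.random.default_rng(0).random(50), 0.0) == 0

    def test_hand_counted(self):
        assert count_below_threshold([0.1, 0.5, 0.69, 0.7, 0.9], 0.7) == 3

    def test_strictness_at_the_boundary(self):
        assert count_below_threshold([0.7, 0.7], 0.7) == 0

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            count_below_threshold([0.5, 1.2], 0.7)
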