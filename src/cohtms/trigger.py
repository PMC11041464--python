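"""Adaptive-threshold trigger state machine and closed-loop session runner.

One *section* runs from a threshold reset to the next stimulus.  At every
1-s analysis tick the latest Coh(β) is compared with the current threshold;
if Coh(β) ≥ threshold a stimulus fires, the threshold resets to its initial
value and analysis pauses for ``pause`` seconds (10 s).  Otherwise the
per-section clock advances one second and, once more than
``modification_onset`` seconds (30 s, wall clock — paused seconds count)
have passed without a stimulus, the threshold is loosened by ``delta``
(0.05) per second down to ``threshold_floor``.  If a section reaches
``recharge_limit`` seconds (60 s, the stimulator's standby limit) without a
stimulus, a recharge marker is logged; it has no algorithmic effect.

The decay law is exact: with no stimulus, after tick t the threshold is
max(floor, θ0 − delta·max(0, t − modification_onset)).

The control condition fires at uniform random integer intervals of 25–35 s,
ignoring coherence for gating but still recording Coh(β) at each stimulus
for analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dsp import DspParams, bandpass_filter, msc_spectrum, EEGWindow
from .synth import MEPModel, simulate_mep

__all__ = [
    "TriggerConfig",
    "TriggerState",
    "StimulusEvent",
    "SessionResult",
    "PartialSessionError",
    "step",
    "run_session",
    "run_session_from_series",
    "run_control_session",
    "count_below_threshold",
]


@dataclass(frozen=True)
class TriggerConfig:
    """Timing constants of the trigger flowchart."""

    initial_threshold: float
    delta: float = 0.05
    modification_onset: float = 30.0
    pause: float = 10.0
    recharge_limit: float = 60.0
    n_stimuli: int = 10
    threshold_floor: float = 0.0
    modification_enabled: bool = True  # False = ablation: threshold never decays

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not self.pause < self.modification_onset <= self.recharge_limit:
            raise ValueError("need pause < modification_onset <= recharge_limit")
        if not 0 <= self.threshold_floor <= self.initial_threshold <= 1:
            raise ValueError("need 0 <= threshold_floor <= initial_threshold <= 1")
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be at least 1")


@dataclass(frozen=True)
class TriggerState:
    current_threshold: float
    seconds_since_last_stimulus: float = 0.0
    stimuli_delivered: int = 0
    phase: str = "analyzing"  # analyzing | paused | done
    pause_remaining: float = 0.0
    recharge_events: tuple[float, ...] = ()

    @staticmethod
    def initial(cfg: TriggerConfig) -> "TriggerState":
        return TriggerState(current_threshold=cfg.initial_threshold)


@dataclass(frozen=True)
class StimulusEvent:
    """One delivered stimulus.  ``modified`` ⇔ the threshold had decayed."""

    time: float
    coh_at_stim: float
    threshold_at_stim: float
    modified: bool
    mep_amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.coh_at_stim < self.threshold_at_stim - 1e-12:
            raise ValueError("event violates the trigger condition coh >= threshold")


@dataclass(frozen=True)
class SessionResult:
    """Ordered stimulus log of one session.

    ``inter_stimulus_intervals`` are consecutive differences over the
    session start (t = 0) and the event times, so interval i is the
    experimental time required for stimulus i — n intervals for n events.
    """

    events: tuple[StimulusEvent, ...]
    inter_stimulus_intervals: tuple[float, ...]
    total_time: float
    condition: str  # coherence_triggered | random_control
    recharge_events: tuple[float, ...] = ()

    @property
    def mep_amplitudes(self) -> np.ndarray:
        return np.array([e.mep_amplitude for e in self.events], dtype=float)

    @property
    def coh_values(self) -> np.ndarray:
        return np.array([e.coh_at_stim for e in self.events], dtype=float)


class PartialSessionError(RuntimeError):
    """EEG source exhausted before the requested number of stimuli."""

    def __init__(self, message: str, events: tuple[StimulusEvent, ...],
                 recharge_events: tuple[float, ...] = ()):
        super().__init__(message)
        self.events = events
        self.recharge_events = recharge_events

    def partial_result(self, condition: str = "coherence_triggered") -> SessionResult:
        return _result_from_events(list(self.events), condition, self.recharge_events)


def step(
    state: TriggerState,
    coh: float,
    cfg: TriggerConfig,
    time: float | None = None,
) -> tuple[TriggerState, StimulusEvent | None]:
    """One analysis tick: compare, then advance the section clock.

    If coh ≥ current_threshold a stimulus event is emitted (MEP amplitude
    unset), the threshold resets to the initial value, the section clock
    zeroes and the machine pauses.  Otherwise the clock advances 1 s and,
    past the modification onset, the threshold decays by delta (never
    below the floor).  Calling while paused or done is a contract
    violation — the runner must skip paused ticks.
    """
    if state.phase != "analyzing":
        raise RuntimeError(f"step() called while phase={state.phase!r}")
    if not 0.0 <= coh <= 1.0:
        raise ValueError(f"coherence must be in [0, 1], got {coh}")

    thr = state.current_threshold
    if coh >= thr:
        delivered = state.stimuli_delivered + 1
        event = StimulusEvent(
            time=float(time) if time is not None else float("nan"),
            coh_at_stim=coh,
            threshold_at_stim=thr,
            modified=thr < cfg.initial_threshold,
        )
        new = replace(
            state,
            current_threshold=cfg.initial_threshold,
            seconds_since_last_stimulus=0.0,
            stimuli_delivered=delivered,
            phase="done" if delivered >= cfg.n_stimuli else "paused",
            pause_remaining=cfg.pause,
        )
        return new, event

    clock = state.seconds_since_last_stimulus + 1.0
    new_thr = thr
    if cfg.modification_enabled and clock > cfg.modification_onset:
        new_thr = max(cfg.threshold_floor, thr - cfg.delta)
    recharges = state.recharge_events
    if clock >= cfg.recharge_limit and clock % cfg.recharge_limit == 0:
        recharges = recharges + (float(time) if time is not None else clock,)
    new = replace(
        state,
        current_threshold=new_thr,
        seconds_since_last_stimulus=clock,
        recharge_events=recharges,
    )
    return new, None


def _advance_pause(state: TriggerState) -> TriggerState:
    """One paused second: the section clock still runs (wall clock)."""
    remaining = state.pause_remaining - 1.0
    return replace(
        state,
        seconds_since_last_stimulus=state.seconds_since_last_stimulus + 1.0,
        pause_remaining=max(0.0, remaining),
        phase="analyzing" if remaining <= 0 else "paused",
    )


def _result_from_events(
    events: list[StimulusEvent], condition: str,
    recharge_events: tuple[float, ...] = (),
) -> SessionResult:
    times = [e.time for e in events]
    intervals = tuple(np.diff([0.0] + times).tolist())
    return SessionResult(
        events=tuple(events),
        inter_stimulus_intervals=intervals,
        total_time=times[-1] if times else 0.0,
        condition=condition,
        recharge_events=recharge_events,
    )


def run_session_from_series(
    coh_series: np.ndarray,
    cfg: TriggerConfig,
    mep: MEPModel | None = None,
    rng: np.random.Generator | None = None,
) -> SessionResult:
    """Drive the state machine over a precomputed per-second Coh(β) series.

    Tick t (1-based) consumes ``coh_series[t-1]``; paused ticks consume a
    value without analysing it.  Raises :class:`PartialSessionError` if the
    series ends before ``cfg.n_stimuli`` events.
    """
    state = TriggerState.initial(cfg)
    events: list[StimulusEvent] = []
    for i, coh in enumerate(np.asarray(coh_series, dtype=float)):
        t = float(i + 1)
        if state.phase == "paused":
            state = _advance_pause(state)
            continue
        state, ev = step(state, min(max(coh, 0.0), 1.0), cfg, time=t)
        if ev is not None:
            if mep is not None:
                ev = replace(
                    ev, mep_amplitude=simulate_mep(ev.coh_at_stim, mep, rng)
                )
            events.append(ev)
        if state.phase == "done":
            return _result_from_events(
                events, "coherence_triggered", state.recharge_events
            )
    raise PartialSessionError(
        f"EEG source exhausted after {len(coh_series)} s with "
        f"{len(events)}/{cfg.n_stimuli} stimuli delivered",
        tuple(events),
        state.recharge_events,
    )


def run_session(
    ch1: np.ndarray,
    ch2: np.ndarray,
    cfg: TriggerConfig,
    mep: MEPModel,
    params: DspParams,
    rng: np.random.Generator | None = None,
    prefiltered: bool = False,
) -> SessionResult:
    """Closed-loop coherence-triggered session over a two-channel recording.

    The stream is filtered once, then analysed in consecutive 1-s windows;
    the loop stops after ``cfg.n_stimuli`` stimuli.  Windows are computed
    lazily so the source is only consumed as far as needed.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if not prefiltered:
        ch1 = bandpass_filter(ch1, params.fs, params.filter_low,
                              params.filter_high, params.filter_order,
                              params.zero_phase)
        ch2 = bandpass_filter(ch2, params.fs, params.filter_low,
                              params.filter_high, params.filter_order,
                              params.zero_phase)
    n_win = int(round(params.fs))
    n_ticks = min(ch1.size, ch2.size) // n_win

    state = TriggerState.initial(cfg)
    events: list[StimulusEvent] = []
    for i in range(n_ticks):
        t = float(i + 1)
        if state.phase == "paused":
            state = _advance_pause(state)
            continue
        w = EEGWindow(ch1[i * n_win:(i + 1) * n_win],
                      ch2[i * n_win:(i + 1) * n_win], fs=params.fs, t_start=t - 1)
        spec = msc_spectrum(w, params.seg_len, params.overlap, params.taper,
                            params.band, params.detrend)
        coh = min(max(spec.coh_beta, 0.0), 1.0)
        state, ev = step(state, coh, cfg, time=t)
        if ev is not None:
            ev = replace(ev, mep_amplitude=simulate_mep(ev.coh_at_stim, mep, rng))
            events.append(ev)
        if state.phase == "done":
            return _result_from_events(
                events, "coherence_triggered", state.recharge_events
            )
    raise PartialSessionError(
        f"EEG source exhausted after {n_ticks} s with "
        f"{len(events)}/{cfg.n_stimuli} stimuli delivered",
        tuple(events),
        state.recharge_events,
    )


def draw_control_intervals(
    n: int,
    rng: np.random.Generator,
    interval_low: float = 25.0,
    interval_high: float = 35.0,
) -> np.ndarray:
    """Uniform integer-second inter-stimulus intervals on [low, high]."""
    if not interval_low < interval_high:
        raise ValueError("need interval_low < interval_high")
    return rng.integers(int(interval_low), int(interval_high) + 1, size=n).astype(float)


def run_control_session(
    ch1: np.ndarray,
    ch2: np.ndarray,
    cfg: TriggerConfig,
    mep: MEPModel,
    params: DspParams,
    rng: np.random.Generator,
    interval_low: float = 25.0,
    interval_high: float = 35.0,
    prefiltered: bool = False,
) -> SessionResult:
    """Control condition: stimuli at random 25–35 s intervals.

    Coherence is never used for gating but Coh(β) of the 1-s window ending
    at each stimulus time is still recorded for analysis, and the MEP is
    drawn at that incidental value.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if not prefiltered:
        ch1 = bandpass_filter(ch1, params.fs, params.filter_low,
                              params.filter_high, params.filter_order,
                              params.zero_phase)
        ch2 = bandpass_filter(ch2, params.fs, params.filter_low,
                              params.filter_high, params.filter_order,
                              params.zero_phase)
    intervals = draw_control_intervals(cfg.n_stimuli, rng, interval_low, interval_high)
    times = np.cumsum(intervals)
    n_win = int(round(params.fs))
    n_avail = min(ch1.size, ch2.size) // n_win

    events: list[StimulusEvent] = []
    for t in times:
        tick = int(round(t))
        if tick > n_avail:
            raise PartialSessionError(
                f"EEG source exhausted at t={tick} s with "
                f"{len(events)}/{cfg.n_stimuli} stimuli delivered",
                tuple(events),
            )
        w = EEGWindow(ch1[(tick - 1) * n_win: tick * n_win],
                      ch2[(tick - 1) * n_win: tick * n_win],
                      fs=params.fs, t_start=tick - 1.0)
        spec = msc_spectrum(w, params.seg_len, params.overlap, params.taper,
                            params.band, params.detrend)
        coh = min(max(spec.coh_beta, 0.0), 1.0)
        events.append(StimulusEvent(
            time=float(tick),
            coh_at_stim=coh,
            threshold_at_stim=0.0,  # no gating in the control condition
            modified=False,
            mep_amplitude=simulate_mep(coh, mep, rng),
        ))
    return _result_from_events(events, "random_control")


def count_below_threshold(values: np.ndarray, threshold: float) -> int:
    """Count of Coh(β) values strictly below the initial threshold.

    A stimulus whose Coh(β) at delivery sits below the initial threshold
    can only have fired after the threshold was modified downward, so this
    count is a proxy for the number of threshold modifications in a
    session log.
    """
    values = np.asarray(values, dtype=float)
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError("coherence values must lie in [0, 1]")
    return int(np.sum(values < threshold))
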