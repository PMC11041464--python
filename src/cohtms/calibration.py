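"""Baseline calibration: the initial triggering threshold.

Before a session, 180 s of resting EEG are partitioned into 180 consecutive
1-s fragments and Coh(β) is computed for each.  The initial threshold is
chosen so that the trigger condition Coh(β) ≥ threshold would have fired
exactly ``target_count`` times (default 6) during the baseline — i.e. once
every 30 s on average, the midpoint of the stimulator's 60-s standby limit.
The selection is the ``target_count``-th largest fragment value: with
distinct values exactly ``target_count`` fragments meet or exceed it; with
ties, at least that many do (ties resolve toward more crossings, matching
the ≥ trigger condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dsp import DspParams, bandpass_filter, coh_beta_series

__all__ = [
    "CalibrationResult",
    "fragment_coh_series",
    "select_threshold",
    "predict_session_time",
    "calibrate",
]


@dataclass(frozen=True)
class CalibrationResult:
    fragment_values: np.ndarray
    initial_threshold: float
    target_count: int = 6
    baseline_duration: float = 180.0
    predicted_session_time: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.fragment_values, dtype=float)
        object.__setattr__(self, "fragment_values", vals)
        if not 0.0 <= self.initial_threshold <= 1.0:
            raise ValueError("initial_threshold must lie in [0, 1]")
        if self.target_count < 1:
            raise ValueError("target_count must be at least 1")


def fragment_coh_series(
    ch1: np.ndarray,
    ch2: np.ndarray,
    params: DspParams,
    prefiltered: bool = False,
) -> np.ndarray:
    """Coh(β) of consecutive non-overlapping 1-s fragments, in order.

    The raw stream is band-pass filtered once as a whole, then partitioned.
    Raises ``ValueError`` if the length is not an integer multiple of the
    sampling rate (the partition must be exact).
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must have identical length")
    n_per = int(round(params.fs))
    if ch1.size % n_per != 0:
        raise ValueError(
            f"length {ch1.size} is not a whole number of 1-s fragments at fs={params.fs}"
        )
    return coh_beta_series(ch1, ch2, params, window_s=1.0, prefiltered=prefiltered)


def select_threshold(values: np.ndarray, target_count: int) -> float:
    """The ``target_count``-th largest value of the fragment series.

    Exactly ``target_count`` values satisfy v ≥ threshold when values are
    distinct; with ties at least that many do, and the returned threshold
    is the smallest order statistic achieving it.
    """
    values = np.asarray(values, dtype=float)
    if target_count < 1:
        raise ValueError("target_count must be at least 1")
    if target_count > values.size:
        raise ValueError(
            f"target_count={target_count} exceeds number of values ({values.size})"
        )
    return float(np.sort(values)[::-1][target_count - 1])


def predict_session_time(
    cal: CalibrationResult, n_stimuli: int, overhead_s: float = 1.0
) -> float:
    """Predicted session time for ``n_stimuli`` stimuli, in seconds.

    One stimulus is expected every baseline_duration / target_count seconds
    (30 s by default), plus a small per-stimulus overhead (default one
    analysis tick).
    """
    if n_stimuli < 0:
        raise ValueError("n_stimuli must be non-negative")
    per_stim = cal.baseline_duration / cal.target_count
    return n_stimuli * per_stim + n_stimuli * overhead_s


def calibrate(
    ch1: np.ndarray,
    ch2: np.ndarray,
    params: DspParams,
    target_count: int = 6,
    n_stimuli: int = 10,
    overhead_s: float = 1.0,
    prefiltered: bool = False,
) -> CalibrationResult:
    """Full baseline calibration from a raw two-channel recording."""
    values = fragment_coh_series(ch1, ch2, params, prefiltered=prefiltered)
    thr = select_threshold(values, target_count)
    cal = CalibrationResult(
        fragment_values=values,
        initial_threshold=min(1.0, thr),
        target_count=target_count,
        baseline_duration=values.size * 1.0,
    )
    return CalibrationResult(
        fragment_values=cal.fragment_values,
        initial_threshold=cal.initial_threshold,
        target_count=cal.target_count,
        baseline_duration=cal.baseline_duration,
        predicted_session_time=predict_session_time(cal, n_stimuli, overhead_s),
    )
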