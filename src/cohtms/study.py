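"""End-to-end synthetic study: baseline → calibration → sessions → summary.

One synthetic participant is a seeded realization of the coupled-source
EEG generator.  Their study day mirrors the evaluation protocol: a 180-s
resting baseline fixes the initial triggering threshold (6 crossings in
180 s), then a coherence-triggered session and a random-interval control
session (25–35 s) deliver ``n_stimuli`` stimuli each, drawing one MEP
amplitude per stimulus.  Optionally an ablation session repeats the
triggered condition with threshold modification disabled, for the
experimental-time comparison.

Sub-seeds for the baseline record, session record, MEP draws and control
intervals are fanned out deterministically from one participant seed, so
conditions and ablations share noise realizations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, calibrate
from .io import RunConfig, spawn_seeds
from .stats import count_cv_reductions, summarize, variance_ratio_test
from .synth import generate_eeg_pair
from .trigger import (
    PartialSessionError,
    SessionResult,
    TriggerConfig,
    run_control_session,
    run_session,
)

__all__ = ["ParticipantResult", "simulate_participant", "simulate_study"]


@dataclass(frozen=True)
class ParticipantResult:
    seed: int
    calibration: CalibrationResult
    triggered: SessionResult
    control: SessionResult
    no_modification: SessionResult | None = None


def liveness_bound(cfg: TriggerConfig) -> float:
    """Worst-case session length with the threshold floor at 0."""
    per_section = (cfg.modification_onset
                   + cfg.initial_threshold / cfg.delta
                   + cfg.pause + 1.0)
    return cfg.n_stimuli * per_section


def simulate_participant(
    run_cfg: RunConfig,
    seed: int,
    include_ablation: bool = False,
    ablation_duration_s: float = 1800.0,
) -> ParticipantResult:
    """Simulate one participant's full study day.

    The triggered and control sessions run over the same session record;
    the ablation (threshold modification off) additionally shares the
    triggered session's threshold and record.  An ablation that exhausts
    the record keeps its partial event log (the no-decay condition has no
    liveness guarantee); the two primary sessions must complete.
    """
    seed_baseline, seed_record, seed_mep, seed_intervals = spawn_seeds(seed, 4)

    baseline_cfg = replace(run_cfg.synth, duration=180.0, seed=seed_baseline)
    b1, b2, _ = generate_eeg_pair(baseline_cfg)
    cal = calibrate(
        b1, b2, run_cfg.dsp,
        target_count=run_cfg.trigger.target_count,
        n_stimuli=run_cfg.trigger.n_stimuli,
    )
    thr = run_cfg.trigger.initial_threshold
    if thr is None:
        thr = cal.initial_threshold
    trig_cfg = run_cfg.trigger.to_trigger_config(thr)

    duration = max(liveness_bound(trig_cfg) + 10.0,
                   run_cfg.trigger.n_stimuli * run_cfg.trigger.interval_high + 10.0)
    if include_ablation:
        duration = max(duration, ablation_duration_s)
    record_cfg = replace(run_cfg.synth, duration=duration, seed=seed_record)
    ch1, ch2, _ = generate_eeg_pair(record_cfg)

    mep = run_cfg.mep
    triggered = run_session(
        ch1, ch2, trig_cfg, mep, run_cfg.dsp,
        rng=np.random.default_rng(seed_mep),
    )
    control = run_control_session(
        ch1, ch2, trig_cfg, mep, run_cfg.dsp,
        rng=np.random.default_rng(seed_intervals),
        interval_low=run_cfg.trigger.interval_low,
        interval_high=run_cfg.trigger.interval_high,
    )

    no_mod: SessionResult | None = None
    if include_ablation:
        ab_cfg = replace(trig_cfg, modification_enabled=False)
        try:
            no_mod = run_session(
                ch1, ch2, ab_cfg, mep, run_cfg.dsp,
                rng=np.random.default_rng(seed_mep),
            )
        except PartialSessionError as exc:
            no_mod = exc.partial_result()

    return ParticipantResult(
        seed=seed,
        calibration=cal,
        triggered=triggered,
        control=control,
        no_modification=no_mod,
    )


def simulate_study(
    run_cfg: RunConfig,
    n_participants: int,
    master_seed: int | None = None,
    include_ablation: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort and assemble the evaluation battery.

    Returns a per-participant table (threshold, per-condition MEP mean/CV,
    variance-ratio p) and a summary dict: the CV-reduction count, and —
    when the ablation runs — pooled per-stimulus time summaries with and
    without threshold modification plus their variance-ratio test.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    seeds = spawn_seeds(
        master_seed if master_seed is not None else run_cfg.seed,
        n_participants,
    )
    rows = []
    results: list[ParticipantResult] = []
    for i, s in enumerate(seeds, start=1):
        r = simulate_participant(run_cfg, s, include_ablation=include_ablation)
        results.append(r)
        trig_sum = summarize(r.triggered.mep_amplitudes)
        ctrl_sum = summarize(r.control.mep_amplitudes)
        ftest = variance_ratio_test(
            r.triggered.mep_amplitudes, r.control.mep_amplitudes,
            alpha=run_cfg.stats.alpha,
        )
        rows.append({
            "participant": i,
            "seed": s,
            "initial_threshold": r.calibration.initial_threshold,
            "mean_coh_triggered": float(np.mean(r.triggered.coh_values)),
            "mean_coh_control": float(np.mean(r.control.coh_values)),
            "mep_mean_triggered": trig_sum.mean,
            "mep_cv_triggered": trig_sum.cv,
            "mep_mean_control": ctrl_sum.mean,
            "mep_cv_control": ctrl_sum.cv,
            "f_statistic": ftest.f_statistic,
            "p_value": ftest.p_value,
            "total_time_triggered": r.triggered.total_time,
            "total_time_control": r.control.total_time,
        })
    table = pd.DataFrame(rows)
    summary: dict = {
        "n_participants": n_participants,
        "cv_reductions": count_cv_reductions(
            zip(table["mep_cv_triggered"], table["mep_cv_control"])
        ),
    }
    if include_ablation:
        with_mod = np.concatenate(
            [r.triggered.inter_stimulus_intervals for r in results]
        )
        without_mod = np.concatenate([
            r.no_modification.inter_stimulus_intervals
            for r in results
            if r.no_modification is not None and len(r.no_modification.events) >= 2
        ])
        sm, sn = summarize(with_mod), summarize(without_mod)
        summary["interval_with_modification"] = {
            "mean": sm.mean, "sd": sm.sd, "cv": sm.cv, "n": sm.n,
        }
        summary["interval_without_modification"] = {
            "mean": sn.mean, "sd": sn.sd, "cv": sn.cv, "n": sn.n,
        }
        ft = variance_ratio_test(without_mod, with_mod, alpha=run_cfg.stats.alpha)
        summary["interval_f_test"] = {
            "f_statistic": ft.f_statistic, "p_value": ft.p_value,
            "significant": ft.significant,
        }
    return table, summary
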