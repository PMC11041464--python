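"""Evaluation statistics: CVs, variance-ratio (F) tests, comparison counts.

The system is judged on dispersion, not level: the coefficient of
variation (CV = SD/mean, sample SD with n−1 denominator) of MEP
amplitudes per condition, and of the per-stimulus experimental times with
and without threshold modification.  Dispersion differences are tested
with a two-sided variance-ratio test: F = s_a²/s_b² against the F
distribution with (n_a−1, n_b−1) degrees of freedom,
p = 2·min(P(F ≤ f), P(F ≥ f)) capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionSummary",
    "VarianceTestResult",
    "summarize",
    "mean_coh",
    "variance_ratio_test",
    "count_cv_reductions",
    "load_reference_mep_cv",
    "load_reference_stimulus_coh",
]


@dataclass(frozen=True)
class ConditionSummary:
    mean: float
    sd: float
    cv: float
    n: int


@dataclass(frozen=True)
class VarianceTestResult:
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    significant: bool
    alpha: float = 0.05


def summarize(values: np.ndarray) -> ConditionSummary:
    """Sample mean, SD (n−1) and CV of amplitudes or intervals."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to summarize")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return ConditionSummary(mean=mean, sd=sd, cv=sd / mean, n=values.size)


def mean_coh(values: np.ndarray) -> float:
    """Arithmetic mean of a Coh(β) series (e.g. the 10 per-stimulus values)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty coherence series")
    return float(np.mean(values))


def variance_ratio_test(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> VarianceTestResult:
    """Two-sided F test for equality of variances.

    Raises ``ValueError`` if either sample has fewer than 2 values or zero
    variance (the ratio is then degenerate).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero variance in a sample: F statistic undefined")
    f = float(va / vb)
    df1, df2 = a.size - 1, b.size - 1
    cdf = sps.f.cdf(f, df1, df2)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return VarianceTestResult(
        f_statistic=f, df1=df1, df2=df2, p_value=p,
        significant=p < alpha, alpha=alpha,
    )


def count_cv_reductions(paired_cvs) -> int:
    """Number of (triggered, control) CV pairs with a strict reduction."""
    pairs = list(paired_cvs)
    if not pairs:
        raise ValueError("no CV pairs given")
    return sum(1 for trig, ctrl in pairs if trig < ctrl)


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("cohtms.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_mep_cv() -> pd.DataFrame:
    """Bundled worked-example MEP-amplitude CVs for 7 participants.

    Columns: participant, triggered_cv, control_cv — the published
    per-participant CV pairs used as regression fixtures for the
    comparison counting.
    """
    return _load_table("reference_mep_cv.csv")


def load_reference_stimulus_coh() -> pd.DataFrame:
    """Bundled worked-example per-stimulus Coh(β) logs for 7 participants.

    Columns: participant, initial_threshold, s1..s10 (Coh(β) at each of
    ten stimuli), printed_mean (the summary as published, 3 decimals).
    """
    return _load_table("reference_stimulus_coh.csv")
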