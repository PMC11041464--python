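"""Synthetic two-channel EEG and MEP amplitudes with known ground truth.

Stands in for the human participant and the stimulation hardware.  The
two channels share a common source with a time-varying mixing weight:

    ch1(t) = a(t)·s(t) + sqrt(1 − a(t)²)·n1(t)
    ch2(t) = a(t)·s(t) + sqrt(1 − a(t)²)·n2(t)

where s, n1, n2 are mutually independent and identically spectrally
shaped (pink background plus band-limited α (8–13 Hz) and β (14–30 Hz)
Gaussian components).  Because source and noise have the same power
spectral density, the population magnitude-squared coherence between the
channels is a⁴ at every frequency with power — an exact, analytically
known target for the estimator.  a(t) drifts as a slow sinusoid so that
inter-channel β coherence waxes and wanes over tens of seconds, the way
resting-state coupling does, producing reproducible threshold-crossing
structure for the trigger.

Motor-evoked potentials are reduced to a scalar peak-to-peak amplitude.
The model encodes the hypothesis under study — MEP dispersion shrinks
when β coherence at the stimulus instant is high — as a relative
dispersion linear in Coh(β):

    amplitude = mu · (1 + ε),  ε ~ N(0, σ(c)²),
    σ(c) = sigma_max − (sigma_max − sigma_min)·c

truncated at zero (amplitudes are magnitudes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SynthConfig", "MEPModel", "generate_eeg_pair", "simulate_mep"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings for one synthetic participant.

    ``mixing_mean`` ± ``drift_amplitude`` must stay inside [0, 1]; the
    drift is a sinusoid with period ``drift_period_s`` seconds.  Band
    powers are relative (coherence is scale-free); ``scale_uv`` only sets
    a µV-ish amplitude for file output.
    """

    fs: float = 500.0
    duration: float = 180.0
    mixing_mean: float = 0.8
    drift_amplitude: float = 0.15
    drift_period_s: float = 40.0
    alpha_power: float = 1.0
    beta_power: float = 1.0
    pink_power: float = 1.0
    scale_uv: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("duration must be at least 1 s")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo = self.mixing_mean - abs(self.drift_amplitude)
        hi = self.mixing_mean + abs(self.drift_amplitude)
        if lo < 0 or hi > 1:
            raise ValueError(
                f"mixing a(t) leaves [0, 1]: range [{lo:.3f}, {hi:.3f}]"
            )
        if min(self.alpha_power, self.beta_power, self.pink_power) < 0:
            raise ValueError("band powers must be non-negative")
        if self.drift_period_s <= 0:
            raise ValueError("drift_period_s must be positive")


def _spectral_envelope(cfg: SynthConfig, freqs: np.ndarray) -> np.ndarray:
    """Amplitude envelope sqrt(S(f)) shared by source and both noises."""
    s = np.zeros_like(freqs)
    f_safe = np.maximum(freqs, 1.0)  # flatten the 1/f rise below 1 Hz
    s += cfg.pink_power / f_safe
    s += np.where((freqs >= 8.0) & (freqs <= 13.0), cfg.alpha_power, 0.0)
    s += np.where((freqs >= 14.0) & (freqs <= 30.0), cfg.beta_power, 0.0)
    s[freqs == 0] = 0.0  # no DC component
    return np.sqrt(s)


def _shaped_noise(rng: np.random.Generator, n: int, envelope: np.ndarray) -> np.ndarray:
    white = rng.standard_normal(n)
    return np.fft.irfft(np.fft.rfft(white) * envelope, n)


def mixing_trace(cfg: SynthConfig, n: int | None = None) -> np.ndarray:
    """Ground-truth a(t), sampled per sample: mean + amp·sin(2πt/period)."""
    if n is None:
        n = int(round(cfg.fs * cfg.duration))
    t = np.arange(n) / cfg.fs
    return cfg.mixing_mean + cfg.drift_amplitude * np.sin(
        2 * np.pi * t / cfg.drift_period_s
    )


def generate_eeg_pair(
    cfg: SynthConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate the coupled channel pair; returns ``(ch1, ch2, a_trace)``.

    Deterministic under ``cfg.seed``: the same config yields bit-identical
    output.  ``a_trace`` is the per-sample ground-truth mixing weight.
    """
    n = int(round(cfg.fs * cfg.duration))
    rng = np.random.default_rng(cfg.seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    env = _spectral_envelope(cfg, freqs)
    s = _shaped_noise(rng, n, env)
    n1 = _shaped_noise(rng, n, env)
    n2 = _shaped_noise(rng, n, env)
    a = mixing_trace(cfg, n)
    if a.min() < 0 or a.max() > 1:
        raise ValueError("mixing a(t) leaves [0, 1]")
    b = np.sqrt(1.0 - a**2)
    ch1 = cfg.scale_uv * (a * s + b * n1)
    ch2 = cfg.scale_uv * (a * s + b * n2)
    return ch1, ch2, a


@dataclass
class MEPModel:
    """Coherence-dependent MEP amplitude model.

    ``mu`` is the baseline amplitude in mV; ``sigma_max``/``sigma_min``
    are the relative dispersions at Coh(β) = 0 and 1.  Draws advance an
    internal generator created from ``seed``, so a fixed seed gives a
    reproducible stimulus-by-stimulus sequence.
    """

    mu: float = 1.0
    sigma_max: float = 0.6
    sigma_min: float = 0.1
    seed: int | None = None
    _rng: np.random.Generator | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if not 0 <= self.sigma_min <= self.sigma_max:
            raise ValueError("need 0 <= sigma_min <= sigma_max")

    @property
    def rng(self) -> np.random.Generator:
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)
        return self._rng

    def sigma(self, c: float) -> float:
        """Relative dispersion at coherence c (linear interpolation)."""
        return self.sigma_max - (self.sigma_max - self.sigma_min) * c


def simulate_mep(
    c: float, model: MEPModel, rng: np.random.Generator | None = None
) -> float:
    """Draw one MEP amplitude (mV) at stimulus-time coherence ``c``.

    Raises ``ValueError`` if c is outside [0, 1].  Negative draws are
    truncated at 0 mV.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"coherence must be in [0, 1], got {c}")
    gen = rng if rng is not None else model.rng
    eps = gen.normal(0.0, model.sigma(c)) if model.sigma(c) > 0 else 0.0
    return max(0.0, model.mu * (1.0 + eps))
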