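"""Two-channel EEG preprocessing and magnitude-squared coherence.

The trigger statistic of the system is Coh(β): the arithmetic mean of the
magnitude-squared coherence (MSC) between two scalp channels (P3 and C4 in
the 10–20 system) over the β band, 14–30 Hz inclusive.  MSC per frequency
bin is

    C_xy(f) = |P_xy(f)|² / (P_xx(f) · P_yy(f))

with P_xx, P_yy the Welch-averaged auto power spectral densities and P_xy
the cross spectral density.  MSC lies in [0, 1] and equals 1 at every bin
when the channels are identical; for a single averaging segment it is
identically 1 regardless of the signals, so at least two segments are
required.

Analysis runs at a 1-s cadence on a 500 Hz stream that has first been
band-passed 1–30 Hz with a fourth-order Butterworth filter (causal by
default — the system it models is online).  Within a 1-s window the default
Welch segmentation is 250-sample segments, 50% overlap, Hann taper: three
segments, 2-Hz bin spacing, nine in-band bins (14, 16, …, 30 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "BETA_BAND",
    "DspParams",
    "EEGWindow",
    "CoherenceSpectrum",
    "bandpass_filter",
    "msc_spectrum",
    "coh_beta",
    "coh_beta_series",
    "read_edf_pair",
]

#: β band endpoints in Hz, inclusive on both sides.
BETA_BAND: tuple[float, float] = (14.0, 30.0)


@dataclass(frozen=True)
class DspParams:
    """All tunable analysis parameters, with the system's defaults.

    ``seg_len``/``overlap``/``taper`` control the Welch estimator inside each
    1-s window; ``filter_*`` control the front-end Butterworth band-pass.
    ``zero_phase`` switches to forward-backward filtering for offline use.
    """

    fs: float = 500.0
    band: tuple[float, float] = BETA_BAND
    filter_low: float = 1.0
    filter_high: float = 30.0
    filter_order: int = 4
    seg_len: int = 250
    overlap: float = 0.5
    taper: str = "hann"
    detrend: str = "constant"
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not 0 < self.filter_low < self.filter_high:
            raise ValueError("need 0 < filter_low < filter_high")
        if self.filter_high >= self.fs / 2:
            raise ValueError(
                f"filter_high={self.filter_high} must be below Nyquist {self.fs / 2}"
            )
        if self.fs <= 2 * self.band[1]:
            raise ValueError("sampling rate must exceed twice the band upper edge")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.seg_len < 2:
            raise ValueError("seg_len must be at least 2 samples")


@dataclass(frozen=True)
class EEGWindow:
    """One fixed-duration two-channel sample block — the unit of analysis.

    Amplitudes are in µV; ``t_start`` is the window's start time in seconds
    from the beginning of the stream.
    """

    samples_ch1: np.ndarray
    samples_ch2: np.ndarray
    fs: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        ch1 = np.asarray(self.samples_ch1, dtype=float)
        ch2 = np.asarray(self.samples_ch2, dtype=float)
        object.__setattr__(self, "samples_ch1", ch1)
        object.__setattr__(self, "samples_ch2", ch2)
        if ch1.ndim != 1 or ch2.ndim != 1:
            raise ValueError("channels must be one-dimensional")
        if ch1.shape != ch2.shape:
            raise ValueError(
                f"channel lengths differ: {ch1.size} vs {ch2.size}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (np.isfinite(ch1).all() and np.isfinite(ch2).all()):
            raise ValueError("non-finite samples in EEG window")

    @property
    def n_samples(self) -> int:
        return int(self.samples_ch1.size)


@dataclass(frozen=True)
class CoherenceSpectrum:
    """Per-bin MSC plus the scalar β-band summary Coh(β).

    ``coh_beta`` is the arithmetic mean of ``msc`` over bins with
    band[0] ≤ f ≤ band[1]; if constructed with ``coh_beta=None`` it is
    filled from the invariant.
    """

    freqs: np.ndarray
    msc: np.ndarray
    band: tuple[float, float] = BETA_BAND
    coh_beta: float | None = None

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        msc = np.asarray(self.msc, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "msc", msc)
        if freqs.shape != msc.shape:
            raise ValueError("freqs and msc must have identical shape")
        if freqs.size and np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(msc < -1e-12) or np.any(msc > 1 + 1e-12):
            raise ValueError("msc values must lie in [0, 1]")
        if self.coh_beta is None:
            object.__setattr__(self, "coh_beta", _band_mean(freqs, msc, self.band))

    def in_band(self) -> np.ndarray:
        """Boolean mask of bins inside the summary band (inclusive)."""
        return (self.freqs >= self.band[0]) & (self.freqs <= self.band[1])


def _band_mean(freqs: np.ndarray, msc: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(
            f"no frequency bins inside band {band}; spectral resolution too coarse"
        )
    return float(np.mean(msc[mask]))


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = 1.0,
    high: float = 30.0,
    order: int = 4,
    zero_phase: bool = False,
) -> np.ndarray:
    """Butterworth band-pass, causal by default.

    Parameters mirror the front end of the online system: ``order=4``,
    1–30 Hz at ``fs=500``.  The filter is designed in second-order
    sections for numerical stability.  ``zero_phase=True`` applies the
    filter forward and backward (``sosfiltfilt``), doubling the effective
    order and removing group delay — appropriate only offline.

    Raises
    ------
    ValueError
        If cutoffs are outside (0, fs/2), order < 1, the input contains
        non-finite samples, or the input is too short.
    """
    x = np.asarray(x, dtype=float)
    if order < 1:
        raise ValueError("filter order must be at least 1")
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= fs / 2:
        raise ValueError(f"cutoff {high} Hz is at or above Nyquist {fs / 2} Hz")
    if not np.isfinite(x).all():
        raise ValueError("non-finite samples in input")
    if x.size <= 3 * order:
        raise ValueError(f"input length {x.size} too short for order {order}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def _n_segments(n: int, seg_len: int, noverlap: int) -> int:
    if n < seg_len:
        return 0
    step = seg_len - noverlap
    return 1 + (n - seg_len) // step


def msc_spectrum(
    w: EEGWindow,
    seg_len: int = 250,
    overlap: float = 0.5,
    taper: str = "hann",
    band: tuple[float, float] = BETA_BAND,
    detrend: str = "constant",
) -> CoherenceSpectrum:
    """Welch magnitude-squared coherence of a two-channel window.

    Segments of ``seg_len`` samples with fractional ``overlap`` are
    detrended (per-segment mean removal by default), tapered, and their
    auto/cross periodograms averaged; MSC is |P_xy|²/(P_xx·P_yy) per bin.

    Raises
    ------
    ValueError
        If fewer than 2 averaging segments fit (single-segment MSC is
        identically 1 and carries no information), or either channel has
        zero variance (the MSC denominator vanishes).
    """
    noverlap = int(round(seg_len * overlap))
    k = _n_segments(w.n_samples, seg_len, noverlap)
    if k < 2:
        raise ValueError(
            f"only {k} averaging segment(s) fit a {w.n_samples}-sample window "
            f"(seg_len={seg_len}, overlap={overlap}); single-segment MSC is "
            "identically 1 — use shorter segments or a longer window"
        )
    if np.ptp(w.samples_ch1) == 0 or np.ptp(w.samples_ch2) == 0:
        raise ValueError("zero-variance channel: MSC denominator is zero")
    freqs, msc = signal.coherence(
        w.samples_ch1,
        w.samples_ch2,
        fs=w.fs,
        window=taper,
        nperseg=seg_len,
        noverlap=noverlap,
        detrend=detrend,
    )
    return CoherenceSpectrum(freqs=freqs, msc=msc, band=band)


def coh_beta(spec: CoherenceSpectrum, band: tuple[float, float] | None = None) -> float:
    """Scalar β-band summary: mean MSC over bins with f_low ≤ f ≤ f_high.

    Both band endpoints are inclusive, so at 2-Hz resolution the 30 Hz bin
    belongs to the band.  Raises ``ValueError`` when no bin falls inside
    the band.
    """
    return _band_mean(spec.freqs, spec.msc, band or spec.band)


def coh_beta_series(
    ch1: np.ndarray,
    ch2: np.ndarray,
    params: DspParams,
    window_s: float = 1.0,
    prefiltered: bool = True,
) -> np.ndarray:
    """Coh(β) over consecutive non-overlapping windows of ``window_s`` seconds.

    The stream is filtered once as a whole (unless ``prefiltered``), then
    partitioned; trailing samples that do not fill a window are dropped.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if not prefiltered:
        ch1 = bandpass_filter(
            ch1, params.fs, params.filter_low, params.filter_high,
            params.filter_order, params.zero_phase,
        )
        ch2 = bandpass_filter(
            ch2, params.fs, params.filter_low, params.filter_high,
            params.filter_order, params.zero_phase,
        )
    n_win = int(round(params.fs * window_s))
    n = min(ch1.size, ch2.size) // n_win
    out = np.empty(n)
    for i in range(n):
        w = EEGWindow(
            ch1[i * n_win : (i + 1) * n_win],
            ch2[i * n_win : (i + 1) * n_win],
            fs=params.fs,
            t_start=i * window_s,
        )
        spec = msc_spectrum(
            w, params.seg_len, params.overlap, params.taper, params.band,
            params.detrend,
        )
        out[i] = spec.coh_beta
    return out


def read_edf_pair(
    path: str, ch1: str = "P3", ch2: str = "C4"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Read two named channels from an EDF file (requires the ``edf`` extra).

    Returns ``(x1, x2, fs)`` with amplitudes in µV.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF input requires mne; install the 'edf' extra"
        ) from exc
    raw = mne.io.read_raw_edf(path, include=[ch1, ch2], preload=True, verbose="error")
    missing = [c for c in (ch1, ch2) if c not in raw.ch_names]
    if missing:
        raise ValueError(f"channels not found in EDF: {missing}")
    data = raw.get_data(picks=[ch1, ch2]) * 1e6  # mne returns volts
    return data[0], data[1], float(raw.info["sfreq"])
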