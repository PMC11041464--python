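import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from cohtms import DspParams, load_reference_mep_cv, load_reference_stimulus_coh

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def dsp_params():
    return DspParams()


@pytest.fixture(scope="session")
def reference_mep_cv():
    return load_reference_mep_cv()


@pytest.fixture(scope="session")
def reference_stimulus_coh():
    return load_reference_stimulus_coh()


def msc_brute_force(x, y, fs, seg_len=250, overlap=0.5, taper="hann"):
    """Independent MSC oracle: explicit segment DFTs, averaged auto/cross
    periodograms, |P_xy|^2/(P_xx P_yy) per bin.

    Per-segment mean removal, then taper, then DFT; all scalings cancel in
    the ratio.
    """
    from scipy.signal import get_window

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    noverlap = int(round(seg_len * overlap))
    step = seg_len - noverlap
    win = get_window(taper, seg_len)
    n_seg = 1 + (x.size - seg_len) // step
    assert n_seg >= 2
    pxx = pyy = pxy = 0.0
    for k in range(n_seg):
        xs = x[k * step : k * step + seg_len]
        ys = y[k * step : k * step + seg_len]
        X = np.fft.rfft((xs - xs.mean()) * win)
        Y = np.fft.rfft((ys - ys.mean()) * win)
        pxx = pxx + (X * np.conj(X)).real
        pyy = pyy + (Y * np.conj(Y)).real
        pxy = pxy + np.conj(X) * Y
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    return freqs, np.abs(pxy) ** 2 / (pxx * pyy)


@pytest.fixture(scope="session")
def msc_oracle():
    return msc_brute_force
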