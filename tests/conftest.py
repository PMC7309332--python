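"""Shared fixtures: canonical signals and reusable (expensive) analysis runs."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from sstwin import (
    AnalysisConfig,
    FrequencyGrid,
    SampledSignal,
    ScaleGrid,
    WaveletSpec,
    analyze,
)

FS = 10.0
DURATION = 180.0
TONE_HZ = 0.3


def make_time(duration=DURATION, fs=FS):
    return np.arange(int(round(duration * fs))) / fs


@pytest.fixture(scope="session")
def time_axis():
    return make_time()


@pytest.fixture(scope="session")
def tone_signal(time_axis):
    return SampledSignal(values=np.cos(2 * np.pi * TONE_HZ * time_axis), sampling_rate=FS)


@pytest.fixture(scope="session")
def chirp_truth(time_axis):
    """Linear chirp 0.2 -> 0.29 Hz over 180 s, with its exact IF."""
    phip = 0.2 + 5e-4 * time_axis
    phi = cumulative_trapezoid(phip, dx=1.0 / FS, initial=0.0)
    sig = SampledSignal(values=np.cos(2 * np.pi * phi), sampling_rate=FS)
    return sig, phip


@pytest.fixture(scope="session")
def am_tone_truth(time_axis):
    """Amplitude-modulated cosine: A(t) = 1 + 0.3 sin(2 pi 0.01 t) at 0.3 Hz."""
    A = 1.0 + 0.3 * np.sin(2 * np.pi * 0.01 * time_axis)
    sig = SampledSignal(values=A * np.cos(2 * np.pi * TONE_HZ * time_axis), sampling_rate=FS)
    return sig, A


@pytest.fixture(scope="session")
def default_wavelet():
    return WaveletSpec()


@pytest.fixture(scope="session")
def default_grid(default_wavelet):
    return ScaleGrid.from_band(0.05, 1.0, 32, default_wavelet.center_frequency)


@pytest.fixture(scope="session")
def default_freq_grid(default_grid, default_wavelet):
    return FrequencyGrid.from_scale_grid(default_grid, default_wavelet.center_frequency)


@pytest.fixture(scope="session")
def tone_products(tone_signal):
    return analyze(tone_signal, AnalysisConfig())


@pytest.fixture(scope="session")
def chirp_products(chirp_truth):
    return analyze(chirp_truth[0], AnalysisConfig())


@pytest.fixture(scope="session")
def am_tone_products(am_tone_truth):
    return analyze(am_tone_truth[0], AnalysisConfig())
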