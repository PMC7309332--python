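"""CWT / phase transform / synchrosqueezing: oracles and invariants."""

import numpy as np
import pytest

from sstwin import FrequencyGrid, SampledSignal, ScaleGrid, WaveletSpec
from sstwin.errors import InconsistentInputError, InvalidGridError, InvalidThresholdError
from sstwin.tfr import cwt, phase_transform, squeeze_weights, synchrosqueeze

from conftest import FS, TONE_HZ, make_time


@pytest.fixture(scope="module")
def broadband_signal():
    t = make_time()
    x = (
        np.cos(2 * np.pi * 0.3 * t)
        + 0.5 * np.sin(2 * np.pi * 0.17 * t)
        + 0.3 * np.cos(2 * np.pi * 0.45 * t + 1.0)
    )
    return SampledSignal(values=x, sampling_rate=FS)


def test_zero_signal_zero_transform(default_wavelet, default_grid):
    sig = SampledSignal(values=np.zeros(1800), sampling_rate=FS)
    W = cwt(sig, default_wavelet, default_grid)
    assert np.all(W.coefficients == 0)
    assert np.all(W.time_derivative == 0)


def test_cwt_linearity(broadband_signal, default_wavelet, default_grid):
    W1 = cwt(broadband_signal, default_wavelet, default_grid).coefficients
    W2 = cwt(broadband_signal.scaled(2.0), default_wavelet, default_grid).coefficients
    np.testing.assert_allclose(W2, 2.0 * W1, rtol=1e-10, atol=1e-12)


def test_cwt_rejects_grid_at_nyquist(default_wavelet):
    sig = SampledSignal(values=np.ones(1800), sampling_rate=FS)
    grid = ScaleGrid.from_band(0.05, 6.0, 8)
    with pytest.raises(InvalidGridError):
        cwt(sig, default_wavelet, grid)


def test_cwt_direct_integration_oracle(broadband_signal, default_wavelet, default_grid):
    """FFT CWT equals trapezoidal integration of the definition on a 5x5 subgrid.

    The subgrid sits at scales where the signal has non-negligible response
    (relative error is meaningless on coefficients at the numerical noise
    floor) and at interior times where the closed-form wavelet support lies
    inside the record.
    """
    x = broadband_signal.values
    t = broadband_signal.time_axis
    W = cwt(broadband_signal, default_wavelet, default_grid)
    worst = 0.0
    for a_target in (2.2, 2.9, 3.3, 4.5, 5.9):
        k = int(np.argmin(np.abs(default_grid.scales - a_target)))
        a = default_grid.scales[k]
        for b in (60.0, 75.0, 90.0, 105.0, 120.0):
            col = int(round(b * FS))
            psi = default_wavelet.time_domain((t - b) / a)
            direct = np.sum(x * np.conj(psi)) / np.sqrt(a) / FS
            worst = max(worst, abs(W.coefficients[k, col] - direct) / abs(direct))
    assert worst <= 1e-6


def test_cwt_tone_peaks_at_tone_scale(tone_products, default_grid):
    """argmax over scales of |W| sits at the scale whose pseudo-frequency is
    nearest the tone frequency, at interior times."""
    W = tone_products.cwt_matrix
    k_expect = int(np.argmin(np.abs(1.0 / default_grid.scales - TONE_HZ)))
    interior_cols = np.flatnonzero(~W.coi_mask.any(axis=0))
    for col in interior_cols[:: max(len(interior_cols) // 7, 1)]:
        assert int(np.argmax(np.abs(W.coefficients[:, col]))) == k_expect


def test_cwt_time_shift_covariance(default_wavelet, default_grid):
    """Shifting the input by k samples shifts all columns by k, away from edges."""
    t = np.arange(2000) / FS
    x = np.cos(2 * np.pi * 0.27 * t) + 0.4 * np.sin(2 * np.pi * 0.33 * t + 0.7)
    k = 7
    W1 = cwt(SampledSignal(values=x[:1800], sampling_rate=FS), default_wavelet, default_grid)
    W2 = cwt(SampledSignal(values=x[k : 1800 + k], sampling_rate=FS), default_wavelet, default_grid)
    tt = W1.time_axis[k:]
    radius = 2.0 * default_wavelet.support_radius * default_grid.scales
    deep = (tt[None, :] - tt[0] > radius[:, None]) & (tt[-1] - tt[None, :] > radius[:, None])
    diff = np.abs(W1.coefficients[:, k:] - W2.coefficients[:, : 1800 - k])
    assert diff[deep].max() <= 1e-6


def test_phase_transform_rejects_negative_gamma(tone_products):
    with pytest.raises(InvalidThresholdError):
        phase_transform(tone_products.cwt_matrix, gamma=-1.0)


def test_phase_transform_masks_below_gamma(tone_products):
    W = tone_products.cwt_matrix
    gamma = 0.1 * np.abs(W.coefficients).max()
    om = phase_transform(W, gamma=gamma)
    assert not np.any(om.defined_mask & (np.abs(W.coefficients) <= gamma))
    assert np.all(np.isfinite(om.omega[om.defined_mask]))


def test_phase_transform_tone_within_half_bin(tone_products, default_freq_grid):
    """For a pure tone the phase transform returns the tone frequency wherever
    the coefficient carries signal (threshold above the finite-record sidelobe
    floor; entries near the floor are energetically negligible)."""
    W = tone_products.cwt_matrix
    om = phase_transform(W, gamma_rel=1e-2)
    interior = om.defined_mask & ~W.coi_mask
    half_bin = TONE_HZ * (np.exp(default_freq_grid.log_step / 2.0) - 1.0)
    assert np.max(np.abs(om.omega[interior] - TONE_HZ)) <= half_bin


def test_phase_transform_tracks_chirp(chirp_truth, chirp_products):
    _, phip = chirp_truth
    W = chirp_products.cwt_matrix
    om = phase_transform(W, gamma_rel=1e-2)
    interior = om.defined_mask & ~W.coi_mask
    rel = np.abs(om.omega - phip[None, :]) / phip[None, :]
    assert np.max(rel[interior]) <= 0.05


def test_synchrosqueeze_shape_mismatch(tone_products, default_freq_grid):
    om = tone_products.omega
    bad = type(om)(
        omega=om.omega[:, :100], defined_mask=om.defined_mask[:, :100], threshold_gamma=om.threshold_gamma
    )
    with pytest.raises(InconsistentInputError):
        synchrosqueeze(tone_products.cwt_matrix, bad, default_freq_grid)


def test_synchrosqueeze_zero_in_zero_out(default_wavelet, default_grid, default_freq_grid):
    sig = SampledSignal(values=np.zeros(1800), sampling_rate=FS)
    W = cwt(sig, default_wavelet, default_grid)
    sst = synchrosqueeze(W, phase_transform(W), default_freq_grid)
    assert np.all(sst.coefficients == 0)


@pytest.mark.parametrize("fixture", ["tone_products", "chirp_products"])
def test_squeezing_mass_conservation(fixture, request):
    """Per time column, reallocated mass equals the weighted sum over defined scales."""
    p = request.getfixturevalue(fixture)
    W = p.cwt_matrix
    weights = squeeze_weights(W.scale_grid)
    mass_in = (W.coefficients * weights[:, None] * p.omega.defined_mask).sum(axis=0)
    mass_out = p.sst.coefficients.sum(axis=0)
    scale = np.abs(mass_in).max()
    assert np.max(np.abs(mass_in - mass_out)) <= 1e-12 * scale


def test_tone_concentration(tone_products, default_freq_grid):
    """>= 95% of squared SST magnitude lies within two bins of the tone."""
    sst = tone_products.sst
    mag2 = np.abs(sst.coefficients) ** 2
    k0 = default_freq_grid.nearest_bin(np.array([TONE_HZ]))[0]
    t = sst.time_axis
    a_tone = 1.0 / TONE_HZ
    r = sst.wavelet.support_radius * a_tone
    cols = (t - t[0] > r) & (t[-1] - t > r)
    frac = mag2[max(k0 - 2, 0) : k0 + 3, cols].sum() / mag2[:, cols].sum()
    assert frac >= 0.95
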