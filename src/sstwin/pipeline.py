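"""End-to-end orchestration: preprocess -> CWT -> squeeze -> ridge -> SSTIF/SSTAM.

Deterministic for a fixed configuration and input; every default that fires is
recorded in the run log carried on the result object.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .config import AnalysisConfig
from .errors import InsufficientDataError, SstWinError
from .ridge import (
    AMEstimate,
    IFEstimate,
    Ridge,
    amplitude_calibration,
    estimate_am,
    estimate_if,
    extract_ridge,
    ridge_boundary_mask,
)
from .signal import SampledSignal, read_signal
from .tfr import CWTMatrix, OmegaMatrix, SSTMatrix, cwt, phase_transform, synchrosqueeze
from .wavelet import FrequencyGrid, ScaleGrid, WaveletSpec


@dataclass(frozen=True)
class AnalysisProducts:
    """Everything one analysis run produces, plus the log of applied defaults."""

    preprocessed: SampledSignal
    cwt_matrix: CWTMatrix
    omega: OmegaMatrix
    sst: SSTMatrix
    ridge: Ridge
    sstif: IFEstimate
    sstam: AMEstimate
    calibration: float
    log: dict


def preprocess(signal: SampledSignal, config: AnalysisConfig) -> tuple[SampledSignal, dict]:
    """Crop the analysis window, resample to the analysis rate, remove the mean."""
    log: dict = {}
    if signal.duration + 0.5 / signal.sampling_rate < config.window_seconds:
        raise InsufficientDataError(
            f"recording of {signal.duration:.1f} s is shorter than the "
            f"{config.window_seconds:.0f} s analysis window"
        )
    if signal.duration > config.window_seconds:
        signal = signal.crop(0.0, config.window_seconds)
        log["cropped_to_seconds"] = config.window_seconds
    if abs(signal.sampling_rate - config.resample_hz) > 1e-9:
        ratio = Fraction(config.resample_hz / signal.sampling_rate).limit_denominator(10000)
        values = resample_poly(signal.values, ratio.numerator, ratio.denominator)
        signal = SampledSignal(
            values=values, sampling_rate=config.resample_hz, units=signal.units, label=signal.label
        )
        log["resampled_to_hz"] = config.resample_hz
    mean = float(np.mean(signal.values))
    signal = SampledSignal(
        values=signal.values - mean,
        sampling_rate=signal.sampling_rate,
        units=signal.units,
        label=signal.label,
    )
    log["removed_mean"] = mean
    return signal, log


def analyze(signal: SampledSignal, config: AnalysisConfig | None = None) -> AnalysisProducts:
    """Run the full single-signal pipeline under *config* (defaults if None)."""
    config = config or AnalysisConfig()
    pre, log = preprocess(signal, config)
    wavelet = WaveletSpec(family=config.wavelet_family, bandwidth=config.wavelet_bandwidth)
    grid = ScaleGrid.from_band(
        config.f_min, config.f_max, config.voices_per_octave, wavelet.center_frequency
    )
    fgrid = FrequencyGrid.from_scale_grid(grid, wavelet.center_frequency)
    log["n_scales"] = grid.n_scales

    W = cwt(pre, wavelet, grid)
    omega = phase_transform(W, gamma=config.gamma_abs, gamma_rel=config.gamma_rel)
    log["gamma"] = omega.threshold_gamma
    sst = synchrosqueeze(W, omega, fgrid)
    ridge = extract_ridge(sst, penalty_lambda=config.penalty_lambda)
    log["penalty_lambda"] = ridge.penalty_lambda
    coi = ridge_boundary_mask(sst, ridge)
    sstif = estimate_if(ridge, coi)
    calib = amplitude_calibration(
        wavelet,
        config.f_min,
        config.f_max,
        config.voices_per_octave,
        config.resample_hz,
        half_width_bins=config.half_width_bins,
        gamma_rel=config.gamma_rel,
    )
    log["amplitude_calibration"] = calib
    sstam = estimate_am(
        sst, ridge, half_width_bins=config.half_width_bins, calibration=calib, boundary_mask=coi
    )
    return AnalysisProducts(
        preprocessed=pre,
        cwt_matrix=W,
        omega=omega,
        sst=sst,
        ridge=ridge,
        sstif=sstif,
        sstam=sstam,
        calibration=calib,
        log=log,
    )


def _write_series_csv(path, time_axis, values, mask) -> None:
    with open(path, "w") as fh:
        fh.write("time_s,value,masked\n")
        for t, v, m in zip(time_axis, values, mask):
            fh.write(f"{t:.6f},{v:.17g},{int(m)}\n")


def _write_matrix_csv(path, matrix, row_axis, col_axis) -> None:
    """Magnitude matrix as CSV: first row = time axis, first column = bin centers."""
    with open(path, "w") as fh:
        fh.write("bin_hz_over_time_s," + ",".join(f"{t:.6f}" for t in col_axis) + "\n")
        for f, row in zip(row_axis, matrix):
            fh.write(f"{f:.8g}," + ",".join(f"{v:.8g}" for v in row) + "\n")


def run_analyze(
    path,
    config: AnalysisConfig | None = None,
    out_dir: str = "sstwin_out",
    fs_override: float | None = None,
    overwrite: bool = False,
) -> AnalysisProducts:
    """Analyze a waveform file and write all products to *out_dir*.

    Layout (fixed): ``sst_magnitude.csv`` (bins x time, axis headers),
    ``sst.npz`` (compressed container with complex coefficients and axes),
    ``sstif.csv`` / ``sstam.csv`` (time_s, value, masked), ``win.csv``
    (one row), ``run_log.json``.
    """
    from .win import compute_win  # local import to avoid a cycle

    config = config or AnalysisConfig()
    if os.path.exists(out_dir) and os.listdir(out_dir) and not overwrite:
        raise SstWinError(f"output directory {out_dir!r} is non-empty; pass overwrite=True")
    os.makedirs(out_dir, exist_ok=True)
    try:
        signal = read_signal(path, fs_override=fs_override)
        products = analyze(signal, config)
    except SstWinError as exc:
        raise type(exc)(f"[{_stage_of(exc)}] {exc}") from exc
    win = compute_win(products.sstam, products.sstif, trim_seconds=config.trim_seconds)

    sst = products.sst
    _write_matrix_csv(
        os.path.join(out_dir, "sst_magnitude.csv"),
        np.abs(sst.coefficients),
        sst.frequency_grid.bin_centers,
        sst.time_axis,
    )
    np.savez_compressed(
        os.path.join(out_dir, "sst.npz"),
        coefficients=sst.coefficients,
        bin_centers_hz=sst.frequency_grid.bin_centers,
        time_axis_s=sst.time_axis,
    )
    _write_series_csv(
        os.path.join(out_dir, "sstif.csv"), products.sstif.time_axis, products.sstif.values,
        products.sstif.boundary_mask,
    )
    _write_series_csv(
        os.path.join(out_dir, "sstam.csv"), products.sstam.time_axis, products.sstam.values,
        products.sstam.boundary_mask,
    )
    with open(os.path.join(out_dir, "win.csv"), "w") as fh:
        fh.write("file,win,window_s,trim_s,n_used\n")
        fh.write(
            f"{path},{win.win:.17g},{win.window_seconds:.6g},{win.trim_seconds:.6g},{win.n_samples_used}\n"
        )
    log = dict(products.log)
    log["config"] = config.to_dict()
    log["win"] = win.win
    with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return products


_STAGES = {
    "InvalidGridError": "tfr_core",
    "InvalidThresholdError": "tfr_core",
    "InconsistentInputError": "tfr_core",
    "DegenerateInputError": "ridge_extract",
    "InvalidBandError": "ridge_extract",
    "InsufficientDataError": "win_index",
    "InvalidIFError": "win_index",
    "FormatError": "io",
    "MissingRateError": "io",
    "InvalidSignalError": "io",
}


def _stage_of(exc: Exception) -> str:
    return _STAGES.get(type(exc).__name__, "pipeline")
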