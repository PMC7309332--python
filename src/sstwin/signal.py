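"""Uniformly sampled waveforms and their plain-text I/O.

A :class:`SampledSignal` is the single in-memory container every stage of the
pipeline consumes: a real-valued, uniformly sampled sequence with its sampling
rate in Hz.  Files are one- or two-column numeric text/CSV; a one-column file
carries its rate in a ``# fs=<Hz>`` header comment or via an explicit override.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, InsufficientDataError, InvalidSignalError, MissingRateError

_MIN_LENGTH = 16
_FS_HEADER = re.compile(r"#\s*fs\s*=\s*([0-9.eE+-]+)")


@dataclass(frozen=True)
class SampledSignal:
    """Uniformly sampled real waveform.

    Parameters
    ----------
    values
        Sample values in signal units (e.g. respiratory flow).
    sampling_rate
        Sampling rate in Hz, strictly positive.
    units
        Free-text unit label, carried through unchanged.
    label
        Optional identifier (file name, subject id).
    """

    values: np.ndarray
    sampling_rate: float
    units: str = "a.u."
    label: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise InvalidSignalError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if vals.ndim != 1 or vals.size < _MIN_LENGTH:
            raise InvalidSignalError(f"signal must be 1-D with >= {_MIN_LENGTH} samples")
        if not np.all(np.isfinite(vals)):
            raise InvalidSignalError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return self.n_samples / self.sampling_rate

    @property
    def time_axis(self) -> np.ndarray:
        """Sample times in seconds from record start."""
        return np.arange(self.n_samples) / self.sampling_rate

    def crop(self, t_start: float, t_stop: float) -> "SampledSignal":
        """Return samples with t_start <= t < t_stop (half-open, seconds)."""
        i0 = int(np.ceil(t_start * self.sampling_rate - 1e-9))
        i1 = int(np.ceil(t_stop * self.sampling_rate - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        if i1 - i0 < _MIN_LENGTH:
            raise InsufficientDataError(
                f"crop [{t_start}, {t_stop}) s keeps {i1 - i0} samples; need >= {_MIN_LENGTH}"
            )
        return replace(self, values=self.values[i0:i1])

    def scaled(self, factor: float) -> "SampledSignal":
        return replace(self, values=self.values * factor)


def read_signal(path, fs_override: float | None = None) -> SampledSignal:
    """Read a waveform from numeric text/CSV.

    Accepts either one value column (rate from ``# fs=<Hz>`` header or
    *fs_override*) or two columns ``time,value`` with uniform spacing
    (verified to 1e-6 relative).  *fs_override* wins over a header.
    """
    header_fs: float | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _FS_HEADER.search(line)
                if m:
                    header_fs = float(m.group(1))
                continue
            parts = re.split(r"[,\s]+", line)
            try:
                rows.append([float(p) for p in parts if p])
            except ValueError as exc:
                raise FormatError(f"{path}: unparseable line {line!r}") from exc
    if not rows:
        raise FormatError(f"{path}: no numeric data")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows) or ncol not in (1, 2):
        raise FormatError(f"{path}: expected 1 or 2 numeric columns")
    data = np.asarray(rows, dtype=float)

    if ncol == 1:
        fs = fs_override if fs_override is not None else header_fs
        if fs is None:
            raise MissingRateError(f"{path}: one-column file needs '# fs=<Hz>' header or an override")
        values = data[:, 0]
    else:
        t, values = data[:, 0], data[:, 1]
        dt = np.diff(t)
        if dt.size == 0 or np.any(dt <= 0):
            raise FormatError(f"{path}: time column not strictly increasing")
        dt0 = np.median(dt)
        if np.max(np.abs(dt - dt0)) > 1e-6 * dt0:
            raise FormatError(f"{path}: non-uniform time axis beyond 1e-6 relative tolerance")
        fs = fs_override if fs_override is not None else 1.0 / dt0
    return SampledSignal(values=values, sampling_rate=float(fs), label=str(path))


def write_signal(signal: SampledSignal, path, two_column: bool = False) -> None:
    """Write a waveform as text; round-trips through :func:`read_signal`."""
    with open(path, "w") as fh:
        if two_column:
            t = signal.time_axis
            for ti, vi in zip(t, signal.values):
                fh.write(f"{ti:.17g},{vi:.17g}\n")
        else:
            fh.write(f"# fs={signal.sampling_rate:.17g}\n")
            fh.write(f"# units={signal.units}\n")
            for vi in signal.values:
                fh.write(f"{vi:.17g}\n")
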