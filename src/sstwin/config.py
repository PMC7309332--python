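"""Analysis configuration: one flat record of every tunable default.

Values can be loaded from a flat JSON file and overridden field-by-field
(the CLI maps flags onto the same names).  Defaults target respiratory flow:
breathing sits near 0.2-0.4 Hz, so the analysis band is [0.05, 1.0] Hz and
the signal is resampled (anti-aliased) to 10 Hz, far above any respiratory
content, before the transform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from .errors import InvalidGridError


@dataclass(frozen=True)
class AnalysisConfig:
    resample_hz: float = 10.0         # analysis rate after anti-aliased resampling
    f_min: float = 0.05               # Hz, lower edge of the analysis band
    f_max: float = 1.0                # Hz, upper edge
    voices_per_octave: int = 32
    gamma_rel: float = 1e-4           # phase-transform threshold, relative to max|W|
    gamma_abs: float | None = None    # absolute override; wins over gamma_rel
    penalty_lambda: float | None = None  # ridge smoothness; None -> grid default
    half_width_bins: int = 2          # SSTAM band half-width
    window_seconds: float = 180.0     # analysed prefix of the recording
    trim_seconds: float = 15.0        # per-edge trim before the WIN variance
    n_boot: int = 1000                # bootstrap replicas for the AUC CI
    ci_level: float = 0.95
    seed: int = 0
    wavelet_family: str = "gaussian"
    wavelet_bandwidth: float = 0.1    # spectral std of the mother wavelet

    def __post_init__(self) -> None:
        if not (0 < self.f_min < self.f_max):
            raise InvalidGridError("need 0 < f_min < f_max")
        if self.f_max >= self.resample_hz / 2:
            raise InvalidGridError(
                f"f_max={self.f_max} Hz must stay below Nyquist {self.resample_hz / 2} Hz"
            )
        for name in ("resample_hz", "voices_per_octave", "half_width_bins", "window_seconds", "n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.trim_seconds < 0 or self.gamma_rel < 0:
            raise ValueError("trim_seconds and gamma_rel must be nonnegative")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path, **overrides) -> "AnalysisConfig":
        """Load a flat JSON key-value config file; *overrides* win."""
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
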