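"""The WIN ventilator-weaning index.

WIN is the variance of the pointwise ratio of the SST-derived amplitude
modulation to the SST-derived instantaneous frequency over the analysis
window:

    WIN = var( SSTAM(t) / SSTIF(t) )

For respiratory flow the SSTAM is read as instantaneous tidal volume and the
SSTIF as instantaneous breathing rate, so the ratio tracks the depth-per-rate
of each moment of breathing and its variance quantifies breathing-pattern
variability.  Lower variability has been associated with weaning failure, so
a *decreased* WIN flags a patient as not ready.

Units: WIN carries (signal units / Hz)^2 and therefore scales with the square
of the recorded flow amplitude.  A published cut-off (88.8841 in the original
68-patient cohort) is meaningful only for the instrument and flow units it
was derived with and is deliberately not hard-coded as a default threshold
anywhere in this package.

The variance is the unbiased sample variance (denominator n - 1) over the
retained samples: boundary-masked columns and a configurable trim at each
edge are excluded first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import InconsistentInputError, InsufficientDataError, InvalidIFError
from .ridge import AMEstimate, IFEstimate
from .signal import SampledSignal


@dataclass(frozen=True)
class WinResult:
    """WIN value plus the windowing it was computed under."""

    win: float
    window_seconds: float
    trim_seconds: float
    n_samples_used: int


def compute_win(am: AMEstimate, iff: IFEstimate, trim_seconds: float = 0.0) -> WinResult:
    """Unbiased sample variance of SSTAM/SSTIF over retained samples.

    Retained = not boundary-masked in either series and at least
    *trim_seconds* away from both ends of the shared time axis.
    """
    if am.values.shape != iff.values.shape or not np.allclose(
        am.time_axis, iff.time_axis, rtol=0, atol=1e-9
    ):
        raise InconsistentInputError("SSTAM and SSTIF must share a time axis")
    if trim_seconds < 0:
        raise ValueError("trim_seconds must be nonnegative")
    t = am.time_axis
    keep = ~(am.boundary_mask | iff.boundary_mask)
    keep &= (t - t[0] >= trim_seconds) & (t[-1] - t >= trim_seconds)
    n = int(np.count_nonzero(keep))
    if n < 2:
        raise InsufficientDataError(
            f"only {n} samples retained after trimming/masking; need >= 2"
        )
    f = iff.values[keep]
    if np.any(f <= 0):
        raise InvalidIFError("nonpositive instantaneous frequency in the retained region")
    r = am.values[keep] / f
    return WinResult(
        win=float(np.var(r, ddof=1)),
        window_seconds=float(t[-1] - t[0] + (t[1] - t[0])),
        trim_seconds=float(trim_seconds),
        n_samples_used=n,
    )


def win_from_signal(signal: SampledSignal, config: AnalysisConfig | None = None) -> WinResult:
    """End-to-end WIN: crop the analysis window, run the SST pipeline, take the variance."""
    from .pipeline import analyze

    config = config or AnalysisConfig()
    products = analyze(signal, config)
    return compute_win(products.sstam, products.sstif, trim_seconds=config.trim_seconds)
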