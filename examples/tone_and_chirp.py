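"""Recover instantaneous frequency and amplitude from signals with known truth.

Builds a pure 0.3 Hz tone, a slow linear chirp, and an amplitude-modulated
tone; runs the synchrosqueezing pipeline; prints the recovery errors of the
SST-derived instantaneous frequency (SSTIF) and amplitude (SSTAM).
"""

import numpy as np
from scipy.integrate import cumulative_trapezoid

from sstwin import AnalysisConfig, SampledSignal, analyze

fs = 10.0
t = np.arange(1800) / fs  # 180 s, the standard analysis window

# --- pure tone: SSTIF should read 0.3 Hz, SSTAM should read 1.0 ---------
tone = SampledSignal(values=np.cos(2 * np.pi * 0.3 * t), sampling_rate=fs)
p = analyze(tone, AnalysisConfig())
ok = ~p.sstif.boundary_mask
print("tone: median SSTIF =", f"{np.median(p.sstif.values[ok]):.4f} Hz",
      "| median SSTAM =", f"{np.median(p.sstam.values[ok]):.4f}")

# --- linear chirp 0.2 -> 0.29 Hz: SSTIF should follow the ramp ----------
phip = 0.2 + 5e-4 * t
phi = cumulative_trapezoid(phip, dx=1 / fs, initial=0.0)
p = analyze(SampledSignal(values=np.cos(2 * np.pi * phi), sampling_rate=fs), AnalysisConfig())
ok = ~p.sstif.boundary_mask
rmse = np.sqrt(np.mean(((p.sstif.values[ok] - phip[ok]) / phip[ok]) ** 2))
print(f"chirp: SSTIF relative RMSE = {100 * rmse:.2f}%  (ramp tracked within grid resolution)")

# --- amplitude-modulated tone: SSTAM should follow A(t) -----------------
A = 1.0 + 0.3 * np.sin(2 * np.pi * 0.01 * t)
p = analyze(SampledSignal(values=A * np.cos(2 * np.pi * 0.3 * t), sampling_rate=fs), AnalysisConfig())
ok = ~p.sstam.boundary_mask
rmse = np.sqrt(np.mean(((p.sstam.values[ok] - A[ok]) / A[ok]) ** 2))
print(f"AM tone: SSTAM relative RMSE = {100 * rmse:.2f}%  (envelope recovered)")
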