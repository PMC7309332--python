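"""Respiration-like AM-FM signal generator with exact ground truth.

The generative model mirrors the adaptive-harmonic signal class the analysis
targets: a clean signal

    f(t) = A(t) * s(2 * pi * phi(t))

where ``s`` is a 2-pi-periodic wave-shape function (non-sinusoidal breaths are
emulated with a small number of harmonics), the amplitude ``A`` and the
instantaneous frequency ``phi'`` vary slowly, satisfying for a declared small
epsilon

    A > 0,  phi' > 0,  |A'| <= eps * phi',  |phi''| <= eps * phi'

(checked numerically on every draw, redrawing up to ten times).  Recorded
signals add heteroscedastic noise ``sigma(t) * Phi(t)`` and, optionally,
ventilator-like transient artifacts: brief machine recalibrations (flat
segments) and invalid respiratory triggers (spurious half-cycles).

The slow modulations are Gaussian white noise low-passed with a Gaussian
spectral taper at the modulation bandwidth and rescaled to sup-norm one, so a
single bandwidth knob controls how fast breathing depth and rate drift.

Defaults describe a resting adult on a T-piece trial: base rate 0.3 Hz
(18 breaths/min), ~10% amplitude and rate modulation drifting over ~50 s
timescales, and a breath shape with 2nd/3rd harmonics at 25%/10% of the
fundamental.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .cohort import LabeledCohort
from .errors import (
    InvalidDesignError,
    InvalidNoiseError,
    InvalidSpecError,
    ModelViolationError,
)
from .signal import SampledSignal


@dataclass(frozen=True)
class WaveShape:
    """2-pi-periodic wave-shape function as a short harmonic series.

    Coefficients are fundamental-first; on construction the series is rescaled
    so the fundamental has unit amplitude.  No constant term exists, so the
    shape has zero mean by construction.
    """

    harmonic_cosine_coeffs: tuple = (1.0, 0.25, 0.10)
    harmonic_sine_coeffs: tuple = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.harmonic_cosine_coeffs, dtype=float)
        s = np.asarray(self.harmonic_sine_coeffs, dtype=float)
        k = max(c.size, s.size)
        if k == 0:
            raise ValueError("wave shape needs at least the fundamental")
        c = np.pad(c, (0, k - c.size))
        s = np.pad(s, (0, k - s.size))
        fund = math.hypot(c[0], s[0])
        if fund == 0:
            raise ValueError("fundamental amplitude must be nonzero")
        object.__setattr__(self, "harmonic_cosine_coeffs", tuple(c / fund))
        object.__setattr__(self, "harmonic_sine_coeffs", tuple(s / fund))

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        out = np.zeros_like(theta)
        for k, (c, s) in enumerate(
            zip(self.harmonic_cosine_coeffs, self.harmonic_sine_coeffs), start=1
        ):
            if c:
                out += c * np.cos(k * theta)
            if s:
                out += s * np.sin(k * theta)
        return out


@dataclass(frozen=True)
class DynamicsSpec:
    """Slow amplitude/frequency dynamics of one subject's breathing."""

    f0: float = 0.3                    # Hz, base breathing rate
    a0: float = 1.0                    # base amplitude, signal units
    am_depth: float = 0.1              # fractional amplitude modulation, [0, 1)
    if_depth: float = 0.1              # fractional frequency modulation, [0, 1)
    modulation_bandwidth: float = 0.02  # Hz, how fast the modulations drift
    epsilon: float = 0.05              # declared slow-variation bound

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.a0 <= 0:
            raise ValueError("f0 and a0 must be positive")
        if not (0 <= self.am_depth < 1 and 0 <= self.if_depth < 1):
            raise ValueError("modulation depths must lie in [0, 1)")
        if self.modulation_bandwidth <= 0 or self.epsilon <= 0:
            raise ValueError("modulation_bandwidth and epsilon must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model sigma(t) * Phi(t).

    kind: 'white' (Gaussian), 'ar1' (colored Gaussian), or 'hetero'
    (white noise under a slowly varying positive envelope).  target_snr_db
    None or +inf means no noise.
    """

    kind: str = "white"
    target_snr_db: float | None = 20.0
    ar_coefficient: float = 0.9
    envelope_depth: float = 0.5       # hetero envelope: 1 + depth*sin(2 pi f_env t)
    envelope_freq: float = 0.005      # Hz

    def __post_init__(self) -> None:
        if self.kind not in ("white", "ar1", "hetero"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not (-1 < self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must lie in (-1, 1)")
        if self.kind == "hetero" and abs(self.envelope_depth) >= 1:
            raise InvalidNoiseError("heteroscedastic envelope must stay positive (|depth| < 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for one signal."""

    A_t: np.ndarray
    phi_t: np.ndarray
    phiprime_t: np.ndarray
    waveshape: WaveShape
    noise: NoiseSpec | None
    seed: int


def _slow_process(n: int, fs: float, bandwidth: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian white noise low-passed with a Gaussian spectral taper, sup-norm one."""
    z = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma_f = bandwidth / 2.0
    taper = np.exp(-(f**2) / (2.0 * sigma_f**2))
    z = np.fft.irfft(np.fft.rfft(z) * taper, n)
    z -= z.mean()
    peak = np.max(np.abs(z))
    return z / peak if peak > 0 else z


def check_slow_variation(
    A: np.ndarray, phiprime: np.ndarray, fs: float, epsilon: float
) -> dict:
    """Numerical residuals of the slow-variation conditions; <= 0 means satisfied."""
    dA = np.gradient(A, 1.0 / fs)
    dphi2 = np.gradient(phiprime, 1.0 / fs)
    bound = epsilon * phiprime
    return {
        "A_positive": bool(np.all(A > 0)),
        "phiprime_positive": bool(np.all(phiprime > 0)),
        "amp_residual": float(np.max(np.abs(dA) - bound)),
        "freq_residual": float(np.max(np.abs(dphi2) - bound)),
    }


def gen_amfm_signal(
    dyn: DynamicsSpec,
    shape: WaveShape | None = None,
    duration: float = 180.0,
    fs: float = 10.0,
    seed: int = 0,
) -> tuple[SampledSignal, GroundTruth]:
    """Draw one AM-FM signal together with its ground truth.

    phi'(t) = f0 * (1 + if_depth * z_f(t)) and A(t) = a0 * (1 + am_depth *
    z_a(t)) with independent slow processes z; phi is the trapezoidal
    integral of phi'; the clean signal is A * s(2 pi phi).  Draws violating
    the slow-variation conditions are redrawn up to ten times.
    """
    if duration < 60.0:
        raise ValueError("duration must be >= 60 s")
    if dyn.f0 * (1 + dyn.if_depth) >= fs / 2:
        raise ValueError("peak instantaneous frequency reaches Nyquist")
    shape = shape or WaveShape()
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    last = None
    for _ in range(10):
        z_f = _slow_process(n, fs, dyn.modulation_bandwidth, rng)
        z_a = _slow_process(n, fs, dyn.modulation_bandwidth, rng)
        phiprime = dyn.f0 * (1.0 + dyn.if_depth * z_f)
        A = dyn.a0 * (1.0 + dyn.am_depth * z_a)
        last = check_slow_variation(A, phiprime, fs, dyn.epsilon)
        ok = (
            last["A_positive"]
            and last["phiprime_positive"]
            and last["amp_residual"] <= 0
            and last["freq_residual"] <= 0
        )
        if ok:
            break
    else:
        raise ModelViolationError(
            f"slow-variation conditions unsatisfiable after 10 draws: {last}"
        )
    phi = cumulative_trapezoid(phiprime, dx=1.0 / fs, initial=0.0)
    values = A * shape(2.0 * np.pi * phi)
    signal = SampledSignal(values=values, sampling_rate=fs, label=f"amfm seed={seed}")
    truth = GroundTruth(
        A_t=A, phi_t=phi, phiprime_t=phiprime, waveshape=shape, noise=None, seed=seed
    )
    return signal, truth


def add_noise(
    signal: SampledSignal, noise: NoiseSpec, seed: int = 0
) -> tuple[SampledSignal, np.ndarray]:
    """Additive noise realisation scaled exactly to the target sample SNR.

    Returns the noisy signal and the noise part (so tests can verify the
    realised SNR and autocorrelation from the stored parts).
    """
    if not np.any(signal.values != 0):
        raise InvalidNoiseError("clean signal is identically zero; SNR undefined")
    if noise.target_snr_db is None or np.isinf(noise.target_snr_db):
        return signal, np.zeros_like(signal.values)
    n = signal.n_samples
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n)
    if noise.kind == "ar1":
        rho = noise.ar_coefficient
        e = lfilter([1.0], [1.0, -rho], e)
        e[0] /= np.sqrt(1.0 - rho**2)  # stationary start
    elif noise.kind == "hetero":
        t = signal.time_axis
        env = 1.0 + noise.envelope_depth * np.sin(2.0 * np.pi * noise.envelope_freq * t)
        if np.any(env <= 0):
            raise InvalidNoiseError("noise envelope must be positive")
        env = env / np.sqrt(np.mean(env**2))
        e = env * e
    p_signal = float(np.mean(signal.values**2))
    p_target = p_signal / 10.0 ** (noise.target_snr_db / 10.0)
    e *= np.sqrt(p_target / np.mean(e**2))
    noisy = SampledSignal(
        values=signal.values + e,
        sampling_rate=signal.sampling_rate,
        units=signal.units,
        label=signal.label,
    )
    return noisy, e


@dataclass(frozen=True)
class ArtifactSpec:
    """Transient ventilator artifacts to inject."""

    n_recalibrations: int = 1          # flat (held-value) segments
    recalibration_seconds: float = 2.0
    n_invalid_triggers: int = 0        # spurious half-cycle bumps
    trigger_seconds: float = 1.5
    trigger_amplitude_rms: float = 2.0  # bump peak as a multiple of signal RMS
    edge_margin_seconds: float = 5.0

    def total_seconds(self) -> float:
        return (
            self.n_recalibrations * self.recalibration_seconds
            + self.n_invalid_triggers * self.trigger_seconds
        )


@dataclass(frozen=True)
class ArtifactEvent:
    kind: str
    t_start: float
    t_stop: float


def inject_artifacts(
    signal: SampledSignal, artifact_spec: ArtifactSpec, seed: int = 0
) -> tuple[SampledSignal, list[ArtifactEvent]]:
    """Insert recalibration-like flat segments and invalid-trigger half-cycles.

    Segments are placed at seeded random times without overlap; the output
    equals the input outside the logged intervals.
    """
    spec = artifact_spec
    if spec.total_seconds() >= 0.1 * signal.duration:
        raise InvalidSpecError("artifact budget exceeds 10% of the record")
    rng = np.random.default_rng(seed)
    fs = signal.sampling_rate
    values = signal.values.copy()
    events: list[ArtifactEvent] = []
    durations = [("recalibration", spec.recalibration_seconds)] * spec.n_recalibrations + [
        ("invalid_trigger", spec.trigger_seconds)
    ] * spec.n_invalid_triggers
    occupied: list[tuple[float, float]] = []
    for kind, dur in durations:
        for _ in range(200):
            t0 = rng.uniform(spec.edge_margin_seconds, signal.duration - spec.edge_margin_seconds - dur)
            if all(t0 + dur <= a or t0 >= b for a, b in occupied):
                break
        else:
            raise InvalidSpecError("could not place non-overlapping artifacts")
        occupied.append((t0, t0 + dur))
        i0, i1 = int(round(t0 * fs)), int(round((t0 + dur) * fs))
        if kind == "recalibration":
            values[i0:i1] = values[i0]
        else:
            amp = spec.trigger_amplitude_rms * float(np.sqrt(np.mean(signal.values**2)))
            bump = amp * np.sin(np.pi * np.arange(i1 - i0) / max(i1 - i0 - 1, 1))
            values[i0:i1] = values[i0:i1] + bump
        events.append(ArtifactEvent(kind=kind, t_start=t0, t_stop=t0 + dur))
    out = SampledSignal(
        values=values, sampling_rate=fs, units=signal.units, label=signal.label
    )
    return out, events


@dataclass(frozen=True)
class SyntheticCohort:
    """Per-subject signals with outcome labels and the seeds that made them."""

    signals: tuple
    truths: tuple
    labels: np.ndarray               # True = weaning success
    subject_seeds: tuple
    effect: float

    def win_scores(self, config=None) -> LabeledCohort:
        """Run the WIN pipeline on every subject and return the labeled scores."""
        from .win import win_from_signal

        wins = [win_from_signal(sig, config).win for sig in self.signals]
        ids = tuple(f"S{i + 1:03d}" for i in range(len(wins)))
        return LabeledCohort(scores=np.asarray(wins), labels=self.labels, subject_ids=ids)


def gen_cohort(
    n_success: int = 45,
    n_failure: int = 23,
    effect: float = 2.0,
    base: DynamicsSpec | None = None,
    seed: int = 0,
    shape: WaveShape | None = None,
    noise: NoiseSpec | None = None,
    duration: float = 180.0,
    fs: float = 10.0,
) -> SyntheticCohort:
    """Two-group cohort of synthetic breathers.

    Failure subjects draw modulation depths from *base*; success subjects use
    both depths multiplied by *effect*, encoding the
    reduced-variability-in-failure hypothesis (*effect* = 1 gives an
    exchangeable null design).  Default group sizes 45/23.
    This is a test fixture for the evaluation machinery, not a physiological
    model of weaning outcome.
    """
    if n_success < 1 or n_failure < 1:
        raise InvalidDesignError("both groups need at least one subject")
    if effect < 1:
        raise InvalidDesignError("effect must be >= 1 (1 = null design)")
    base = base or DynamicsSpec()
    if base.am_depth * effect >= 1 or base.if_depth * effect >= 1:
        raise InvalidDesignError("effect pushes a modulation depth past 1")
    if noise is None:
        noise = NoiseSpec(kind="white", target_snr_db=20.0)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_success + n_failure)
    labels = np.concatenate([np.ones(n_success, bool), np.zeros(n_failure, bool)])
    signals, truths, seeds = [], [], []
    for label, child in zip(labels, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        dyn = base if not label else base.__class__(
            f0=base.f0,
            a0=base.a0,
            am_depth=base.am_depth * effect,
            if_depth=base.if_depth * effect,
            modulation_bandwidth=base.modulation_bandwidth,
            epsilon=base.epsilon,
        )
        sig, truth = gen_amfm_signal(dyn, shape, duration=duration, fs=fs, seed=sub_seed)
        if noise.target_snr_db is not None and not np.isinf(noise.target_snr_db):
            sig, _ = add_noise(sig, noise, seed=sub_seed + 1)
            truth = GroundTruth(
                A_t=truth.A_t,
                phi_t=truth.phi_t,
                phiprime_t=truth.phiprime_t,
                waveshape=truth.waveshape,
                noise=noise,
                seed=sub_seed,
            )
        signals.append(sig)
        truths.append(truth)
        seeds.append(sub_seed)
    return SyntheticCohort(
        signals=tuple(signals),
        truths=tuple(truths),
        labels=labels,
        subject_seeds=tuple(seeds),
        effect=effect,
    )
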