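# Methods

## Signal model

`sstwin` targets one-component adaptive harmonic signals

    f(t) = A(t) · s(2π φ(t)),

with `s` a zero-mean 2π-periodic wave-shape function, amplitude `A > 0` and
instantaneous frequency `φ′ > 0` varying slowly relative to the oscillation:
`|A′| ≤ ε φ′` and `|φ″| ≤ ε φ′` for a small ε (0.05 by default throughout).
Recordings are modelled as `g = f + σ(t)Φ(t)` with `Φ` a stationary process
and `σ` a slowly varying envelope. Exactly one oscillatory component is
assumed; harmonics of a non-sinusoidal wave shape are *not* separate
components, and the ridge extraction below is built to stay on the
fundamental rather than merging or hopping to harmonics.

## Estimator

**Preprocessing.** The first `window_seconds` (default 180 s) of the record
are analysed. Input is resampled with an anti-aliased polyphase filter to
`resample_hz` (default 10 Hz — respiration lives below 1 Hz, so this loses
nothing and cuts compute ~10× for 100 Hz monitor data) and the mean is
removed.

**Analytic CWT.** The mother wavelet is a Gaussian spectral window centred
at 1 cycle with spectral std 0.1 (configurable; a compactly supported bump
family is also provided). Its energy at negative frequencies is ~1e-22, far
below the 1e-10 analyticity budget the phase transform needs. Scales form a
geometric grid, 32 voices per octave, spanning pseudo-frequencies
[0.05, 1.0] Hz by default. Coefficients use L2 normalisation (a^-1/2) and
are computed by frequency-domain multiplication; the time derivative ∂_b W
is obtained spectrally (multiplication by 2πif), never by finite
differences, which would amplify noise. Boundaries: the signal is
reflect-padded by six envelope stds of the largest scale (so periodic
wrap-around is negligible at interior times) and cropped back; a
cone-of-influence mask (within three envelope stds of an edge, per scale) is
carried downstream.

**Phase transform and squeezing.** `ω(a,b) = Im[∂_b W / W]/2π` where
`|W| > γ`, with γ defaulting to 1e-4 · max|W| (absolute override available).
Defined coefficients are reallocated to the geometric frequency bin (one bin
per scale, same span) nearest `ω` in log frequency, ties to the lower bin,
accumulating `W · a^{-3/2} Δa`. Out-of-band ω values are clipped to the edge
bins so reallocation exactly conserves the per-column weighted mass (tested
to 1e-12 relative). A numerical caveat: entries with `|W|` just above the
default γ are dominated by finite-record sidelobes and carry arbitrary
frequencies. They are energetically irrelevant (for a pure tone, 99.9999% of
squared squeezed mass lands within ±2 bins of the tone), but entrywise
claims about ω only hold above a larger threshold (γ ≈ 1e-2 · max|W|), which
is what the entrywise tests use.

**Ridge, SSTIF, SSTAM.** The ridge maximises
`Σ_b log(|S(c(b),b)| + δ) − λ Σ_b (Δ log ξ)²` over all bin paths, solved
exactly by Viterbi dynamic programming (numba-compiled inner loop; verified
against exhaustive path enumeration on small matrices). δ is the smallest
positive normal double. The default λ prices a one-bin-per-column jump at
1 nat — roughly 10% of the on/off-ridge log-magnitude contrast of noise-free
squeezed matrices — which holds the path on the fundamental against 2nd/3rd
harmonics at the default wave shape. SSTIF is the ridge's bin-centre trace,
unsmoothed; its resolution is therefore one grid bin (2.2% at 32
voices/octave). SSTAM is `calibration · |Σ S|` over ±2 bins around the
ridge; the squeezing measures are already folded into S. The calibration
constant is computed numerically, once per wavelet/grid/rate configuration,
by running the full pipeline on a unit-amplitude cosine at the geometric
mid-frequency of the band and inverting the median interior band mass —
self-consistent and wavelet-agnostic, and accurate to <2% across the middle
half of the band. Columns inside the cone of influence at the ridge's own
scale are masked.

**WIN.** `WIN = var(SSTAM/SSTIF)` as the *unbiased* sample variance
(denominator n−1) over samples that are unmasked and at least `trim_seconds`
(default 15 s) from each window edge, at the analysis rate (not per breath).
WIN scales with the square of the flow amplitude, so absolute values — and
any cut-off derived from them — are instrument- and unit-specific. No
default decision threshold is shipped.

**Cohort evaluation.** Positive class = weaning success; score ≥ threshold
predicts success (decreased variability associates with failure). AUC is the
exact Mann–Whitney concordance `P(s⁺ > s⁻) + ½P(tie)` via average ranks.
The confidence interval is a percentile bootstrap (default 1000 replicas)
with *stratified* per-class resampling — at 23 subjects in the smaller
class, unstratified resampling would occasionally produce single-class
replicas. The operating point maximises Youden's J with ties broken toward
the smallest cutoff. Percentile intervals can in principle miss the point
estimate; the summary flags this rather than clamping.

## Synthetic respiration generator

`φ′ = f0(1 + m_f z_f)` and `A = a0(1 + m_a z_a)` where `z` are independent
Gaussian white processes low-passed with a Gaussian spectral taper
(std = bandwidth/2) and rescaled to sup-norm one; φ integrates φ′
trapezoidally; the clean signal is `A·s(2πφ)`. Defaults: f0 = 0.3 Hz
(18 breaths/min), a0 = 1, m_a = m_f = 0.1, bandwidth 0.02 Hz (~50 s drift
timescale), wave shape = cosine + 0.25·2nd + 0.10·3rd harmonic — a resting
adult with a mildly non-sinusoidal breath. Every draw is checked numerically
against the slow-variation conditions at ε = 0.05, redrawing up to ten times
(deterministic per seed) before erroring. Noise kinds: white Gaussian, AR(1)
colored, or white under a slowly varying positive envelope; realisations are
rescaled so the sample SNR matches the target exactly. Artifacts emulate
ventilator interruptions: held-value flat segments (machine recalibration)
and additive half-cycle bumps (invalid triggers), placed at seeded random
times without overlap, budgeted below 10% of the record, with a returned
event log.

Two-group cohorts multiply both modulation depths by `effect` in the success
group (effect = 1 is an exchangeable null). Default sizes 45 success / 23
failure with 20 dB white noise at 10 Hz, 180 s per subject. This is a
fixture for the evaluation machinery, not a physiological model of weaning:
real flow signals differ in wave-shape changes across breaths, apnea and
sigh events, nonstationary noise, and between-subject differences in f0 and
units — so passing synthetic tests demonstrates correct estimation under the
stated model, not clinical performance.

## Numerical choices and degenerate inputs

- Frequency-bin assignment: nearest in log frequency, exact halves to the
  lower bin; non-positive phase-transform values go to the lowest bin.
- All-zero matrices: transforms return zeros; ridge extraction raises
  (no dominant curve exists).
- DP ties broken toward the smaller bin index, matching the enumeration
  oracle's lexicographic order.
- Determinism: every stochastic step takes an explicit seed; per-subject
  seeds derive from a master seed via seed sequences. Reruns are
  byte-identical.
- Problem sizes in the shipped tests and acceptance script (180 s at 10 Hz;
  cohorts of 68; 5 effect and 20 null cohort replicates; 1000 bootstrap
  replicas) are chosen to exercise every property at the model's natural
  scale while keeping a full run in minutes on one core.

## Known limitations

- SSTIF resolution is bounded by the bin grid; raising voices/octave
  sharpens it at linear cost.
- The estimator assumes one component; concurrent oscillators (e.g.
  cardiogenic oscillations inside the band) would need multi-ridge
  extraction, which is out of scope.
- IF estimates degrade when φ′ varies fast relative to ε — intrinsic to
  synchrosqueezing.
- WIN is deliberately sensitive to amplitude variability, which makes it
  sensitive to transient artifacts as well: a single 2 s recalibration
  segment produces a genuine local dip in SSTAM over one wavelet support
  (~16 s at 0.3 Hz) whose variance contribution can exceed the baseline
  variability of a mildly modulated signal, changing WIN severalfold. With
  strong baseline variability the same artifact is proportionally minor.
  Artifact-aware masking would mitigate this but is not part of the defined
  estimator; the robustness probe in the acceptance script reports the
  measured change honestly.
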