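"""Compute the WIN breathing-variability index on synthetic respiration.

Generates a respiration-like AM-FM signal (non-sinusoidal breath shape, slow
amplitude and rate drift), adds measurement noise, computes WIN =
var(SSTAM/SSTIF) over the first 3 minutes, and shows how WIN grows with the
underlying breathing variability — the property its use as a weaning
predictor relies on.
"""

from sstwin import DynamicsSpec, NoiseSpec, WaveShape, add_noise, gen_amfm_signal, win_from_signal

shape = WaveShape()  # cosine fundamental + 25% 2nd + 10% 3rd harmonic

for depth in (0.05, 0.1, 0.2):
    dyn = DynamicsSpec(am_depth=depth, if_depth=depth)
    sig, truth = gen_amfm_signal(dyn, shape, duration=180.0, fs=10.0, seed=42)
    noisy, _ = add_noise(sig, NoiseSpec(kind="white", target_snr_db=20.0), seed=43)
    result = win_from_signal(noisy)
    print(
        f"modulation depth {depth:.2f}: WIN = {result.win:.5f} "
        f"({result.n_samples_used} samples retained)"
    )
print("WIN rises with breathing-pattern variability; a low WIN flags reduced")
print("variability, the pattern associated with weaning failure.")
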