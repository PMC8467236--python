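"""Compute the 14-feature vector of one synthetic recording.

Pipeline per epoch: 50 Hz notch -> wavelet-packet band decomposition ->
Shannon wavelet entropy and energy per band, plus the four band-energy
ratios (heart rate theta/alpha, brain perfusion alpha/delta, neural
activity beta/theta, synchronization delta/theta). Epoch vectors are then
averaged into one row per recording.
"""

from apneabands import (NotchSpec, SynthSpec, apply_notch, aggregate_recording,
                        extract_band_coefficients, feature_vector,
                        generate_recording, segment_epochs)

rec = generate_recording(
    SynthSpec(duration_s=90.0, mains_amplitude=10.0, noise_sd=0.5, seed=3),
    subject_id="demo", label="normal")

vectors = []
for epoch in segment_epochs(rec, epoch_seconds=30):
    clean = apply_notch(epoch, NotchSpec(f0=50, q=30, fs=rec.fs))
    bc = extract_band_coefficients(clean)
    vectors.append(feature_vector(bc, rec.subject_id, rec.label))

agg = aggregate_recording(vectors)
print(f"{rec.subject_id}: {len(vectors)} epochs of 30 s, label={rec.label}")
for name, value in agg.values.items():
    print(f"  {name:24s} {value:12.4f}")
# Entropies are dimensionless (0 .. ln N per band); energies are summed
# squared coefficients (uV^2 scale), largest where the generator put power
# (alpha/beta for the "normal" profile); ratios compare band energies.
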