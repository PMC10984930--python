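"""Accelerometer-to-classifier pipeline on simulated tremor signals.

Simulates tri-axial 62.5 Hz signals for a high-amplitude ("tremor") and a
low-amplitude ("rest") population, extracts FFT features (dominant
frequency, total power, band-power fractions per axis), and classifies the
feature table with 10-fold cross-validation.
"""

from anrs import (
    evaluate_kfold,
    extract_fft_features,
    simulate_tremor_signal,
    tremor_feature_table,
)

sig = simulate_tremor_signal(duration=4.0, fs=62.5, tremor_freq=5.0, amplitude=1.0,
                             noise_sd=0.2, seed=1)
rec = extract_fft_features(sig)
print(f"samples per axis: {len(sig.axes[0])} (4 s at 62.5 Hz)")
print(f"x-axis dominant frequency: {rec.values['x_dom_freq']:.2f} Hz (programmed 5 Hz)")
print(f"x-axis power fraction in 3-7 Hz band: {rec.values['x_band_3_7']:.3f}")

table = tremor_feature_table(n_per_class=30, amp_high=1.0, amp_low=0.0, noise_sd=0.2, seed=1)
report = evaluate_kfold(table, k=10, r=0.002, seed=1)
print(f"10-fold CV accuracy, tremor vs rest: {report.mean_accuracy:.3f}")
print(
    "the oscillation concentrates power in the tremor band, so the feature\n"
    "table separates the two populations almost perfectly."
)
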