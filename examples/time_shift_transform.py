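"""The closed-form phase code, and recovering it from onset timing.

First prints the expected processing-time shift for a range of prediction
strengths (oscillation amplitude 1.5, 4 Hz): stronger predictions are
processed earlier, up to a quarter cycle.  Then generates synthetic
sentences whose word-to-word intervals were *built* with a planted
(amplitude, phase), and shows that the grid-search regression recovers the
planted values by out-of-sample R².
"""
import numpy as np

from stimcon import fit_expected_onsets, relative_time_shift
from stimcon.fixtures import generate_onset_trains

print("prediction ->  expected shift (ms)")
for p in (0.0, 0.25, 0.5, 1.0, 1.5):
    print(f"   {p:4.2f}          {1000 * relative_time_shift(p, 1.5, 0.0, 4.0):7.1f}")

planted_amp, planted_phi = 1.5, -0.15 * np.pi
trains = generate_onset_trains(
    seed=12, n_sentences=40, amplitude=planted_amp, phase_rad=planted_phi,
    noise_sd_s=0.0,
)
fit = fit_expected_onsets(
    trains, amplitudes=(1.0, 1.5, 2.0),
    phases_rad=(-0.25 * np.pi, -0.15 * np.pi, 0.0), n_splits=50,
)
print(f"\nplanted  amplitude {planted_amp}, phase {planted_phi / np.pi:+.2f} pi")
print(f"recovered amplitude {fit.best_amplitude}, "
      f"phase {fit.best_phase_rad / np.pi:+.2f} pi "
      f"(R2 {fit.r2.max():.3f} vs covariate-only {fit.baseline_r2:.3f})")
print("\nOn noiseless data the planted oscillation is recovered exactly; with"
      "\ntiming noise the R2 surface flattens into a ridge and the argmax can"
      "\ndrift a grid step, so alignment is identified only approximately.")
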