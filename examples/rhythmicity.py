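"""Predictable words can arrive early and the brain response stays rhythmic.

Drives the network with a 10-word, 4 Hz train (Gaussian inputs) whose
odd-numbered words are shifted in time, and measures the 4 Hz magnitude of
the summed rectified activation.  When the shifted odd words are the
predictable ones (low-high), the response is most rhythmic with the odd
words *early*; with unpredictable odd words (high-low) the peak moves to
*late* offsets — matching the natural tendency of speakers to produce
predictable words earlier.
"""
import numpy as np

from stimcon.experiments import rhythmicity_experiment

offsets = np.arange(-60.0, 61.0, 20.0)
for pattern in ("low-high", "high-low"):
    grid = rhythmicity_experiment(pattern, offsets, [0.8])
    print(f"{pattern:>9}: 4 Hz power peaks at odd-word offset "
          f"{grid.peak_offset(0.8):+.0f} ms")
print("\nNegative = predictable odd words presented early still give the most"
      "\nrhythmic internal response; the isochrony lives in the brain, not the input.")
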