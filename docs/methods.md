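# Methods

## Model and assumptions

`stimcon` simulates a single layer of word nodes whose activation is the
sum of four terms — bottom-up evidence, top-down prediction feedback, an
activity-dependent inhibition gate, and a fixed sinusoidal excitability
drive — integrated on a fixed 1 ms grid. The model makes deliberately
strong simplifications: the oscillator has constant amplitude, frequency
and phase (no phase resetting, no coupling to acoustics, no multi-frequency
hierarchy), the language model is a fixed word-to-word transition matrix
(no learning), and word input is an abstract confidence trace rather than
an acoustic waveform.

### Integration and events

Activation is computed per step from the *previous* step's
time-since-activation `Ta`; a node whose activation reaches the threshold
(default 1.0) *from below* generates an event and resets `Ta` to 0 at that
sample. While activation stays at or above threshold no further events
fire and `Ta` is not re-reset. Before a node's first event `Ta` is treated
as infinite, so untouched nodes sit at base inhibition. The three gate
regimes are half-open intervals `[0, 20)`, `[20, 100)`, `[100, ∞)` ms; the
boundary value 100 ms belongs to the base regime.

### Oscillation and phase convention

The excitability drive is the real projection `Am·cos(2πωt + φ)` (the
imaginary part of the complex exponential plays no role). φ is chosen so
the excitability peak coincides with the maximum of the first word's input:
the end of a linear ramp, or the mean of a Gaussian. With 125 ms ramps at
4 Hz this puts word *onsets* at the oscillation troughs and ramp peaks at
the crests, which is what makes the feedback-free efficiency map optimal at
isochronous presentation.

The closed-form time-shift transform uses the sine convention (phase
measured from the ascending zero-crossing), under which
`−Am·sin(2πωT + φ) = p` inverts to
`T = (arcsin(p/−Am) − φ)/(2πω)` on the principal branch. The same
sinusoid in the cosine convention is `oscillation(t, φ − π/2)`; the
consistency test uses that identity. Predictions exceeding `Am` are
clamped to the branch limit with a warning, since grid searches legitimately
cross the limit.

### Feedback dynamics

Feedback is triggered once per word occurrence, by the first threshold
crossing of the corresponding node while it receives non-zero bottom-up
input; crossings caused by feedback alone trigger nothing. The triggered
projection is the node's prediction row scaled by the gain (1.5), arriving
0.9 cycles after the crossing. The projected signal *holds* at full
strength for as long as the source node remains suprathreshold (shifted by
the same delay) and then decays linearly at 0.01 units/ms; concurrent
projections sum. The hold makes the feedback span roughly one theta cycle
(hold ≈ 90 ms plus ≤ 150 ms decay), which is what lets a strongly
predicted node reach threshold on feedback alone near the excitability
peak — the mechanism behind the asymmetric efficiency maps and the
/da/–/ga/ race. Modelling the feedback as an instantaneous pulse that
decays from arrival was considered and rejected: its maximum possible
drive (0.75 − decay) never reaches threshold together with the
oscillation, so none of the feedback-only behaviour the model is meant to
produce would exist.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `amplitude` (Am) | 1.0 | activation | oscillation amplitude; with base inhibition −0.2 the subthreshold margin at the peak is 0.2 |
| `frequency_hz` (ω) | 4.0 | Hz | stimulation/entrainment rate; 6.25 or 10 Hz in the syllable experiment |
| `base_inhib` | −0.2 | activation | resting inhibition; the gate returns −3×, +3×, 1× this value |
| `excitation_window_ms` | 20 | ms | post-event net-excitation window |
| `recovery_ms` | 100 | ms | return to base inhibition |
| `activation_threshold` | 1.0 | activation | event threshold |
| `delay_cycles` | 0.9 | cycles | feedback arrival delay (slightly under one cycle: predictions prepare for slightly-early input) |
| `decay_per_ms` | 0.01 | 1/ms | linear feedback decay after the hold |
| `gain` | 1.5 | – | weight on prediction probabilities |
| `dt_ms` | 1.0 | ms | integration step; all timing results are quantised to it |

Stimuli: 125 ms linear ramps (0 → intensity, endpoint included, zero
immediately after) at a 250 ms SOA, or Gaussians with σ = 42 ms truncated
at ±3σ (the truncated mass is < 1.2 % of the peak). Overlapping inputs on
a node sum.

## Experiments

**Efficiency maps.** /I eat XXX/ with the final word swept over onset
delay (−125…+125 ms, 1 ms) and intensity. *Supra-time* is the first event
of the target node at or after its stimulus onset; *iso-time* adds the
delay (time on the oscillation clock). The panel-line "at a threshold of
0.53" is read as the contour at stimulus intensity 0.53. The compression
statistic divides the width of a delay window by the iso-time range across
it; the window defaults to the maximal contiguous delay run on which
iso-time is monotone (non-strict, either direction), and a window may also
be supplied explicitly — the /cake/ analysis window of record is
−59…+72 ms. Cells where a pre-onset feedback-driven crossing holds the
node above threshold through the stimulus have no post-onset crossing and
are undefined by this definition; this makes the non-monotone tail of a
fed-back target's line *flat* on the oscillation clock, so the full-line
ratio here exceeds the monotone-section ratio rather than undercutting it.

**Saturation intensity.** Minimal ramp intensity activating a
feedback-free node at every onset phase (bisection per onset over one
cycle, 0.01 intensity and 1 ms onset resolution). The 1 ms discretisation
makes the result (2.2) a step coarser than an idealised continuous sweep.

**Rhythmicity.** Ten-word chains at 4 Hz with Gaussian inputs; constant
(0 / 0.8) or alternating word-to-word predictability. The pattern labels
read off per-word predictability along the sentence, so in `low-high` the
shifted odd words (0-based 1, 3, …) are the highly predicted ones. The
"overall activity" is the sum over nodes of zero-rectified activation;
spectra are Hann-tapered magnitudes of the mean-removed 0.5–2.5 s segment,
and the statistic is the magnitude at the bin nearest the stimulation rate.
Whether the original analysis rectified, z-scored or weighted differently
is not recoverable from the text; this minimal reading reproduces the
qualitative peak shifts (leftward for `low-high`, rightward for
`high-low` at middle intensities).

**/da/–/ga/ categorisation.** Two unit-intensity entrainers at the
presentation rate (which also sets ω), then an ambiguous mixture splitting
a fixed intensity between the /da/ and /ga/ nodes. Decoders: first node to
cross threshold after the mixture onset (ties at the same sample resolved
by higher activation, deeper ties and no-events coded 0.5), and the graded
index (da − ga)/(da + ga) of zero-rectified mean activity over 500 ms,
min-max scaled per delay sweep. The grid search sweeps mixture proportion,
feedback onset, feedback decay and a temporal offset of the final sound
(protocol grids 10:5:80 %, 0.1:0.1:1.0 cycles, 0:0.01:0.1, −0.05:0.01:0.05 s)
and scores R² = 1 − RSS/TSS; the baseline is a fixed-frequency sinusoid
(amplitude, phase, mean) optionally snapped to {0, 0.5, 1}. AIC uses the
Gaussian-residual form `n·ln(RSS/n) + 2k` with k = 4 for the network model
and k = 3 for the sinusoid (the swept parameter counts).

## Synthetic data

The study's behavioural dataset and speech corpus are access-restricted,
so two seeded generators provide structured stand-ins; passing tests shows
the *machinery* recovers planted structure, not that the model fits any
real data.

* **Onset trains** plant exactly the regression's linear model: interval =
  0.32 s + transform(prediction; planted Am, φ, sentence rate) − 0.02·rate
  + 0.5·previous-duration + Gaussian noise, with predictions from a
  right-skewed Beta(0.6, 3) and rates ~N(4, 0.5) Hz. With zero noise the
  grid search recovers the planted (Am, φ) with R² = 1; with noise the R²
  surface is a near-flat ridge (grid-point differences ~10⁻⁴, since the
  transform is close to affine in its parameters over [0, 1]) and the
  argmax may drift a grid step. Real corpora add everything these trains
  lack: prosody, syntax beyond bigrams, speaker variation, measurement
  error.
* **Behavioural curves** are damped sinusoids at the presentation rate
  (amplitude 0.35, τ = 0.25 s — bias strongest at short delays) with
  binomial noise at 24 trials per delay, min-max normalised per rate.
  They emulate the shape of phase-dependent categorisation data, not any
  subject's responses.

## Numerical choices and degenerate inputs

Events are sample-quantised; all printed timing numbers therefore carry
±1 ms grid granularity, and the compression ratios inherit it. A
perfectly flat contour yields an infinite ratio flagged as perfect
compression; windows containing undefined cells raise a gap error rather
than silently interpolating. The /da/–/ga/ graded index returns 0 when
both nodes are silent; a constant behavioural curve scores R² = 0 against
a mean-only sinusoid and AIC returns −∞ (with a warning) at zero RSS.
Config files reject unknown keys; an empty file reproduces the default
parameterisation exactly.

## Known limitations

* The compression ratio of the feedback-free /I/ target computes to ~2.9
  here; its contour edges are fixed by hard threshold geometry (required
  drive at the oscillation peak), so the value is insensitive to small
  convention changes and was left as computed.
* The full-line /cake/ ratio is *larger* than the monotone-section ratio
  in this implementation (the flat feedback-driven tail adds window but no
  range — see Efficiency maps above).
* The transform's de-skewing of prediction distributions holds for samples
  with mass near full predictability (the steep arcsin branch spreads the
  bulk); for right-skewed samples with a thin tail toward 1 it slightly
  *increases* |skew|.
* With the default gain, a first word at intensities well below 1 never
  fires, so sentence simulations assume unit-intensity context words.
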